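"""Synthetic-data generators for every stage of the fecundity pipeline.

The generators emulate the data structure of a natural-variation fecundity
study in Drosophila recombinant inbred lines (RILs): a two-way RIL panel
genotyped at ~100 SNPs on three chromosomes, daily egg counts per female
over a 14-day assay under two larval diets, four-genotype quantitative
complementation crosses (and two-class RNAi designs), and qPCR Ct plates
with a reference gene.

Egg-laying trajectories follow a rise-then-fall curve that is linear in its
parameters on the transformed scale:

    ln(E[eggs] + 1) = b0 + b1*ln(age) + b2*age,   b1 > 0 > b2,

which peaks at age = -b1/b2 and declines thereafter.  Line, vial and fly
random effects act on this transformed (log) scale and are drawn with a
lognormal mean-one correction (mean -sigma^2/2) so that the configured
mean trajectory is exactly the population mean of the generated counts.
Daily counts are negative-binomial around the back-transformed mean
(Poisson and noise-free available as limiting cases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import brentq

from .genmap import GeneticMap, GenotypeMatrix, recombination_fraction

__all__ = [
    "QTLSpec",
    "FecundityGeneratorConfig",
    "triangular_coefficients",
    "intercept_for_total",
    "simulate_ril_genotypes",
    "simulate_fecundity",
    "simulate_complementation",
    "simulate_qpcr",
]

EGG_COLUMNS = ["line", "genotype_class", "environment", "vial", "fly", "day", "eggs"]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QTLSpec:
    """A single planted QTL.

    ``variance_fraction`` is the target proportion of among-line variance
    (on the transformed line-mean scale) attributable to the QTL; the
    allelic effect size is derived from it.  ``additive_effect_by_environment``
    optionally gives *relative* per-environment effect weights (they are
    normalized to root-mean-square 1, so the overall variance fraction is
    preserved while allowing genotype-by-environment structure).
    """

    chrom: object
    position_cm: float
    variance_fraction: float = 0.35
    additive_effect_by_environment: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.variance_fraction < 1.0):
            raise ValueError("variance_fraction must be in [0, 1)")


@dataclass(frozen=True)
class FecundityGeneratorConfig:
    """Knobs of the egg-count generator.

    All standard deviations are on the transformed ln(eggs+1) scale.
    ``env_peak_height`` maps environment name -> peak daily egg count;
    its keys define the environments of the assay.
    """

    peak_day: float = 4.0
    decline_rate: float = -0.35
    env_peak_height: dict = field(
        default_factory=lambda: {"yeast_0.2": 28.0, "yeast_0.6": 45.0}
    )
    line_sd: float = 0.30
    ril_sd: float = 0.15
    vial_sd: float = 0.15
    fly_sd: float = 0.15
    count_model: str = "negative_binomial"  # | "poisson" | "deterministic"
    nb_dispersion: float = 20.0
    n_vials: int = 10
    n_flies: int = 1
    n_days: int = 14
    seed: int = 0

    def __post_init__(self):
        for name in ("line_sd", "ril_sd", "vial_sd", "fly_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if not (1.0 < self.peak_day < self.n_days):
            raise ValueError("peak_day must lie strictly inside the assay window")
        if self.decline_rate >= 0:
            raise ValueError("decline_rate must be negative (curve must decline)")
        if self.count_model not in ("negative_binomial", "poisson", "deterministic"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.count_model == "negative_binomial" and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if min(self.n_vials, self.n_flies) < 1:
            raise ValueError("n_vials and n_flies must be >= 1")
        if any(h <= 0 for h in self.env_peak_height.values()):
            raise ValueError("peak heights must be > 0")


def triangular_coefficients(peak_height: float, peak_day: float, decline_rate: float):
    """(b0, b1, b2) of the linearized rise-then-fall curve with the given
    peak egg count, peak day and decline rate (b2)."""
    b2 = float(decline_rate)
    b1 = -b2 * float(peak_day)
    b0 = math.log(peak_height + 1.0) - b1 * math.log(peak_day) - b2 * peak_day
    return b0, b1, b2


def _curve_total(b0: float, b1: float, b2: float, day_range=(1.0, 14.0)) -> float:
    x = np.linspace(day_range[0], day_range[1], 1301)
    mu = np.clip(np.expm1(b0 + b1 * np.log(x) + b2 * x), 0.0, None)
    return float(simpson(mu, x=x))


def intercept_for_total(
    total: float, b1: float, b2: float, day_range=(1.0, 14.0)
) -> float:
    """Solve for the intercept b0 so the back-transformed curve integrates
    to ``total`` eggs over ``day_range``.  Monotone in b0; bisection."""
    if total <= 0:
        raise ValueError("total fecundity target must be > 0")
    f = lambda b0: _curve_total(b0, b1, b2, day_range) - total
    lo, hi = -10.0, 10.0
    while f(hi) < 0:
        hi += 5.0
    while f(lo) > 0:
        lo -= 5.0
    return brentq(f, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# RIL genotypes
# ---------------------------------------------------------------------------

def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_lines: int,
    seed: int,
    missing_rate: float = 0.0,
    map_function: str = "haldane",
) -> GenotypeMatrix:
    """Simulate fully inbred two-way RIL genomes as parental mosaics.

    Each line starts each chromosome on parent A or B with probability 1/2;
    between adjacent markers the allele switches with the RIL-expanded
    recombination fraction r* = 2r/(1+2r) of the Haldane (or Kosambi)
    fraction for the cM distance.  No heterozygotes are produced.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cols = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome(chrom)
        pos = sub["cm"].to_numpy(float)
        rstar = recombination_fraction(np.diff(pos), map_function, ril=True)
        state = np.empty((n_lines, len(pos)), dtype=bool)
        state[:, 0] = rng.random(n_lines) < 0.5
        if len(pos) > 1:
            switches = rng.random((n_lines, len(pos) - 1)) < rstar
            state[:, 1:] = state[:, [0]] ^ np.logical_xor.accumulate(switches, axis=1)
        for j, mk in enumerate(sub["marker"]):
            cols[mk] = np.where(state[:, j], "B", "A").astype(object)
    calls = pd.DataFrame(cols, index=[f"RIL{i + 1:02d}" for i in range(n_lines)])
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = calls.mask(mask)
    return GenotypeMatrix(calls, gmap)


# ---------------------------------------------------------------------------
# egg-count generators
# ---------------------------------------------------------------------------

def _centered_normal(rng, sd, size):
    """Normal draw with lognormal mean-one correction: mean -sd^2/2."""
    if sd == 0:
        return np.zeros(size)
    return rng.normal(-0.5 * sd * sd, sd, size)


def _draw_counts(rng, mu, config: FecundityGeneratorConfig) -> np.ndarray:
    mu = np.clip(mu, 0.0, None)
    if config.count_model == "deterministic":
        return np.rint(mu).astype(np.int64)
    if config.count_model == "poisson":
        return rng.poisson(mu)
    k = config.nb_dispersion
    return rng.negative_binomial(k, k / (k + mu))


def _qtl_marker(gmap: GeneticMap, qtl: QTLSpec) -> str:
    sub = gmap.chromosome(qtl.chrom)
    pos = sub["cm"].to_numpy(float)
    if not (pos.min() <= qtl.position_cm <= pos.max()):
        raise ValueError("QTL position lies outside the map")
    return str(sub["marker"].iloc[int(np.argmin(np.abs(pos - qtl.position_cm)))])


def simulate_fecundity(
    genotypes: GenotypeMatrix,
    qtl: QTLSpec | None,
    config: FecundityGeneratorConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Daily egg counts for every RIL x environment x vial x fly x day.

    The QTL (if any) shifts the transformed line-level intercept by
    +/- delta_e/2 by allele, with delta calibrated so the expected fraction
    of among-line variance attributable to the QTL equals
    ``qtl.variance_fraction``.  The allele at the marker nearest the QTL
    position defines each line's ``genotype_class`` (``A`` carries the
    high-fecundity allele).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lines = list(genotypes.line_ids)
    envs = list(config.env_peak_height)
    L, E = len(lines), len(envs)
    D, V, F = config.n_days, config.n_vials, config.n_flies

    # per-environment base curves
    base = {
        e: triangular_coefficients(h, config.peak_day, config.decline_rate)
        for e, h in config.env_peak_height.items()
    }

    line_eff = _centered_normal(rng, config.line_sd, L)

    qtl_shift = np.zeros((L, E))
    classes = np.array(["-"] * L, dtype=object)
    if qtl is not None and qtl.variance_fraction > 0:
        if config.line_sd == 0:
            raise ValueError(
                "variance_fraction > 0 is infeasible with line_sd = 0: "
                "the QTL would explain all among-line variance"
            )
        v = qtl.variance_fraction
        delta = 2.0 * config.line_sd * math.sqrt(v / (1.0 - v))
        if qtl.additive_effect_by_environment:
            w = np.array(
                [qtl.additive_effect_by_environment.get(e, 1.0) for e in envs], float
            )
            w = w / math.sqrt(float(np.mean(w**2)))
        else:
            w = np.ones(E)
        mk = _qtl_marker(genotypes.gmap, qtl)
        allele = genotypes.calls[mk].to_numpy(object)
        obs = np.isin(allele, ("A", "B"))
        x = np.where(allele == "A", 0.5, -0.5)
        x[~obs] = 0.0  # untyped lines carry no planted effect
        qtl_shift = delta * np.outer(x, w)
        classes = allele.copy()
        classes[~obs] = "-"
    elif qtl is not None:
        mk = _qtl_marker(genotypes.gmap, qtl)  # still validate position

    vial_eff = _centered_normal(rng, config.vial_sd, (L, E, V))
    fly_eff = _centered_normal(rng, config.fly_sd, (L, E, V, F))

    days = np.arange(1, D + 1, dtype=float)
    eta = np.empty((L, E, V, F, D))
    for ei, e in enumerate(envs):
        b0, b1, b2 = base[e]
        curve = b0 + b1 * np.log(days) + b2 * days
        eta[:, ei] = (
            curve[None, None, None, :]
            + line_eff[:, None, None, None]
            + qtl_shift[:, ei, None, None, None]
            + vial_eff[:, ei, :, None, None]
            + fly_eff[:, ei, :, :, None]
        )
    counts = _draw_counts(rng, np.expm1(eta), config)

    li, ei, vi, fi, di = np.unravel_index(np.arange(counts.size), counts.shape)
    lines_arr = np.array(lines, object)
    envs_arr = np.array(envs, object)
    df = pd.DataFrame(
        {
            "line": lines_arr[li],
            "genotype_class": classes[li],
            "environment": envs_arr[ei],
            "vial": [f"{l}_{e}_v{v + 1}" for l, e, v in zip(lines_arr[li], envs_arr[ei], vi)],
            "day": di + 1,
            "eggs": counts.ravel(),
        }
    )
    df["fly"] = df["vial"] + "_f" + pd.Series(fi + 1, dtype=str)
    return df[EGG_COLUMNS]


def simulate_complementation(
    class_totals: dict,
    config: FecundityGeneratorConfig,
    seed: int | None = None,
    n_rils: int = 6,
) -> pd.DataFrame:
    """Egg counts for a quantitative-complementation or RNAi cross design.

    ``class_totals`` maps genotype-class label -> target mean total
    fecundity (eggs over days 1..n_days).  Four-class complementation
    designs use labels like ``A/Bal, B/Bal, A/Def, B/Def``; classes sharing
    the prefix before ``/`` (the RIL allele) share a pool of ``n_rils``
    RILs of origin, whose random effects (sd ``ril_sd``) are common to
    both crosses of that allele.  Designs whose labels carry no ``/``
    (e.g. control/RNAi) are one genetically uniform cross per class: a
    single stock each with no stock-level random effect (vial and fly
    effects still apply).  Records carry RIL-of-origin and vial
    identifiers for the "RIL and vial nested within RIL" random-effect
    structure.
    """
    if len(class_totals) < 2:
        raise ValueError("need at least 2 genotype classes")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    D, V, F = config.n_days, config.n_vials, config.n_flies
    days = np.arange(1, D + 1, dtype=float)
    b2 = config.decline_rate
    b1 = -b2 * config.peak_day

    allelic = all("/" in cls for cls in class_totals)
    pools = {}
    for cls in class_totals:
        key = cls.split("/")[0] if allelic else cls
        if key not in pools:
            if allelic:
                pools[key] = {
                    f"{key}-ril{i + 1}": eff
                    for i, eff in enumerate(_centered_normal(rng, config.ril_sd, n_rils))
                }
            else:
                pools[key] = {f"{key}-stock": 0.0}

    rows = []
    for cls, total in class_totals.items():
        b0 = intercept_for_total(float(total), b1, b2, (1.0, float(D)))
        curve = b0 + b1 * np.log(days) + b2 * days
        pool = pools[cls.split("/")[0] if allelic else cls]
        for ril, ril_eff in pool.items():
            vial_eff = _centered_normal(rng, config.vial_sd, V)
            fly_eff = _centered_normal(rng, config.fly_sd, (V, F))
            eta = (
                curve[None, None, :]
                + ril_eff
                + vial_eff[:, None, None]
                + fly_eff[:, :, None]
            )
            counts = _draw_counts(rng, np.expm1(eta), config)
            for v in range(V):
                vial = f"{cls}_{ril}_v{v + 1}"
                for f in range(F):
                    fly = f"{vial}_f{f + 1}"
                    for d in range(D):
                        rows.append(
                            (ril, cls, "assay", vial, fly, d + 1, counts[v, f, d])
                        )
    return pd.DataFrame(rows, columns=EGG_COLUMNS)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_log2fc: float,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_sd: float = 0.2,
    seed: int | None = None,
    groups: tuple = ("group1", "group2"),
    target_gene: str = "target",
    reference_gene: str = "Rpl32",
    tissue: str = "head",
    target_base_ct: float = 22.0,
    reference_base_ct: float = 16.0,
) -> pd.DataFrame:
    """Ct plate for a two-group target-vs-reference comparison.

    ``true_log2fc`` is the log2 expression of ``groups[1]`` relative to
    ``groups[0]``; under perfect doubling efficiency the target Ct of
    group 2 is shifted by ``-true_log2fc`` cycles, the reference gene is
    unaffected by group.  Noise is nested: a per-biological-replicate
    loading shift shared by both genes (sd = ct_sd, cancels in delta-Ct),
    gene-specific biological noise (sd = ct_sd) and technical noise
    (sd = ct_sd/2) within biological replicates.
    """
    if n_bio < 2:
        raise ValueError("n_bio must be >= 2")
    if n_tech < 1:
        raise ValueError("n_tech must be >= 1")
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(groups):
        for b in range(1, n_bio + 1):
            loading = rng.normal(0.0, ct_sd)
            for gene, base in ((target_gene, target_base_ct), (reference_gene, reference_base_ct)):
                ct_mean = base + loading + rng.normal(0.0, ct_sd)
                if gene == target_gene and gi == 1:
                    ct_mean -= true_log2fc
                for t in range(1, n_tech + 1):
                    ct = ct_mean + rng.normal(0.0, ct_sd / 2.0)
                    rows.append((f"{g}_b{b}", g, tissue, gene, b, t, ct))
    return pd.DataFrame(
        rows, columns=["sample", "group", "tissue", "gene", "bio_rep", "tech_rep", "ct"]
    )
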