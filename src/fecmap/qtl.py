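"""Multiple-imputation interval mapping on RIL line totals.

The scan tests, at every marker and pseudomarker, the full model

    y = M_i + E + M_i:E + eps      against      y = E + eps,

where ``y`` is estimated total fecundity per line x environment, ``M_i``
the (imputed) RIL genotype at position *i* and ``E`` the larval
environment.  Genotypes at pseudomarkers and untyped markers are drawn
jointly along each chromosome from a two-state Markov chain whose
transition probabilities are RIL-expanded Haldane recombination fractions
(Kosambi optional); 50 imputations per position by default, combined by
averaging the likelihood ratio across imputations:
LOD = log10(mean_i 10^LOD_i) (a mean-of-LODs alternative is available).

Genome-wide significance comes from permuting line identities of the
phenotype (keeping each line's environment pair intact) and taking the
(1-alpha) quantile of the null maximum LOD.  Support intervals are
LOD-drop intervals (default 3) around the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genmap import GeneticMap, GenotypeMatrix, recombination_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "PseudomarkerGrid",
    "ImputationSet",
    "LODProfile",
    "build_grid",
    "conditional_genotype_probabilities",
    "draw_imputations",
    "scan",
    "permutation_threshold",
    "variance_explained",
    "lod_support_interval",
    "scan_pipeline",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class PseudomarkerGrid:
    """Ordered evaluation positions: all markers plus pseudomarkers
    inserted so adjacent grid points are at most ``step_cm`` apart."""

    table: pd.DataFrame  # columns: chrom, cm, marker (None at pseudomarkers)
    step_cm: float

    @property
    def n_positions(self) -> int:
        return len(self.table)

    def chromosome_slices(self):
        tab = self.table
        for chrom in tab["chrom"].unique():
            idx = np.flatnonzero((tab["chrom"] == chrom).to_numpy())
            yield chrom, idx


def build_grid(gmap: GeneticMap, step_cm: float = 3.0) -> PseudomarkerGrid:
    if step_cm <= 0:
        raise ValueError("step_cm must be > 0")
    rows = []
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome(chrom)
        pos = sub["cm"].to_numpy(float)
        grid = set(np.round(pos, 10))
        lo, hi = pos.min(), pos.max()
        n_steps = int(np.ceil((hi - lo) / step_cm))
        if n_steps > 0:
            grid.update(np.round(np.linspace(lo, hi, n_steps + 1), 10))
        marker_at = dict(zip(np.round(pos, 10), sub["marker"]))
        for p in sorted(grid):
            rows.append((chrom, float(p), marker_at.get(p)))
    return PseudomarkerGrid(
        pd.DataFrame(rows, columns=["chrom", "cm", "marker"]), float(step_cm)
    )


@dataclass
class ImputationSet:
    """Joint genotype draws on the grid: ``genotypes`` has shape
    (n_imputations, n_lines, n_positions), codes 0 = A, 1 = B."""

    genotypes: np.ndarray
    grid: PseudomarkerGrid
    line_ids: list
    seed: int

    @property
    def n_imputations(self) -> int:
        return self.genotypes.shape[0]


def _chain_inputs(genotypes: GenotypeMatrix, grid: PseudomarkerGrid, map_function):
    """Per chromosome: grid index array, transition r* per interval, and
    observation codes (lines x grid positions; -1 where unobserved)."""
    codes = genotypes.codes()
    marker_col = {m: j for j, m in enumerate(genotypes.gmap.markers)}
    out = []
    for chrom, idx in grid.chromosome_slices():
        sub = grid.table.iloc[idx]
        pos = sub["cm"].to_numpy(float)
        rstar = recombination_fraction(np.diff(pos), map_function, ril=True)
        obs = np.full((genotypes.n_lines, len(idx)), -1, dtype=np.int8)
        for t, m in enumerate(sub["marker"]):
            if m is not None and not (isinstance(m, float) and np.isnan(m)):
                obs[:, t] = codes[:, marker_col[m]]
        out.append((chrom, idx, rstar, obs))
    return out


def _forward(obs: np.ndarray, rstar: np.ndarray) -> np.ndarray:
    """Filtered state distributions, shape (T, L, 2); stationary prior 0.5."""
    L, T = obs.shape
    f = np.empty((T, L, 2))
    cur = np.full((L, 2), 0.5)
    for t in range(T):
        if t > 0:
            r = rstar[t - 1]
            cur = np.stack(
                [cur[:, 0] * (1 - r) + cur[:, 1] * r, cur[:, 0] * r + cur[:, 1] * (1 - r)],
                axis=1,
            )
        o = obs[:, t]
        cur = cur.copy()
        cur[o == 0, 1] = 0.0
        cur[o == 1, 0] = 0.0
        cur /= cur.sum(axis=1, keepdims=True)
        f[t] = cur
    return f


def conditional_genotype_probabilities(
    genotypes: GenotypeMatrix,
    grid: PseudomarkerGrid,
    map_function: str = "haldane",
) -> np.ndarray:
    """P(allele A) for every line at every grid position, conditioning on
    all observed markers of the chromosome (forward-backward smoothing)."""
    L = genotypes.n_lines
    probs = np.empty((L, grid.n_positions))
    for chrom, idx, rstar, obs in _chain_inputs(genotypes, grid, map_function):
        T = len(idx)
        f = _forward(obs, rstar)
        b = np.ones((L, 2))
        probs_c = np.empty((T, L))
        for t in range(T - 1, -1, -1):
            post = f[t] * b
            probs_c[t] = post[:, 0] / post.sum(axis=1)
            if t > 0:
                # fold emission at t into the backward message for t-1
                e = b.copy()
                o = obs[:, t]
                e[o == 0, 1] = 0.0
                e[o == 1, 0] = 0.0
                r = rstar[t - 1]
                b = np.stack(
                    [e[:, 0] * (1 - r) + e[:, 1] * r, e[:, 0] * r + e[:, 1] * (1 - r)],
                    axis=1,
                )
                b /= np.maximum(b.sum(axis=1, keepdims=True), 1e-300)
        probs[:, idx] = probs_c.T
    return probs


def draw_imputations(
    genotypes: GenotypeMatrix,
    grid: PseudomarkerGrid,
    n_imputations: int = 50,
    seed: int = 0,
    map_function: str = "haldane",
) -> ImputationSet:
    """Joint draws along each chromosome from the conditional chain
    (forward-filter backward-sample), consistent with observed markers."""
    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    rng = np.random.default_rng(seed)
    L = genotypes.n_lines
    I = n_imputations
    G = np.empty((I, L, grid.n_positions), dtype=np.int8)
    for chrom, idx, rstar, obs in _chain_inputs(genotypes, grid, map_function):
        T = len(idx)
        f = _forward(obs, rstar)  # (T, L, 2)
        z = np.empty((T, I, L), dtype=np.int8)
        p1 = f[T - 1][:, 1][None, :]  # (1, L)
        z[T - 1] = (rng.random((I, L)) < p1).astype(np.int8)
        for t in range(T - 2, -1, -1):
            r = rstar[t]
            znext = z[t + 1]
            # T[j, z_next]: prob of moving from state j to the sampled next state
            t0 = np.where(znext == 0, 1 - r, r)
            t1 = np.where(znext == 0, r, 1 - r)
            p0 = f[t][:, 0][None, :] * t0
            p1 = f[t][:, 1][None, :] * t1
            z[t] = (rng.random((I, L)) * (p0 + p1) >= p0).astype(np.int8)
        G[:, :, idx] = np.transpose(z, (1, 2, 0))
    return ImputationSet(G, grid, list(genotypes.line_ids), seed)


@dataclass
class LODProfile:
    """Per-position LOD scores with effect estimates and metadata."""

    table: pd.DataFrame  # chrom, cm, marker, lod, ve, effect_<env>...
    environments: list
    n_imputations: int
    combine: str
    n_obs: int
    threshold: float | None = None
    alpha: float | None = None
    null_max_lod: np.ndarray | None = field(default=None, repr=False)

    def peak(self) -> pd.Series:
        i = self.table["lod"].idxmax(skipna=True)
        return self.table.loc[i]

    @property
    def max_lod(self) -> float:
        return float(self.table["lod"].max(skipna=True))


def _phenotype_matrix(totals: pd.DataFrame, line_ids: list):
    envs = sorted(totals["environment"].unique())
    piv = totals.pivot_table(index="line", columns="environment", values="total")
    missing_lines = [l for l in line_ids if l not in piv.index]
    if missing_lines:
        raise ValueError(f"totals missing lines: {missing_lines}")
    piv = piv.loc[line_ids, envs]
    if piv.isna().any().any():
        raise ValueError("every line needs a total in every environment")
    return piv.to_numpy(float), envs


def _scan_design(imputations: ImputationSet, envs, skip_mask=None):
    """Batched orthonormal bases of the full-model design at every
    (position, imputation), plus the reduced-model basis."""
    G = imputations.genotypes  # (I, L, P)
    I, L, P = G.shape
    E = len(envs)
    n = L * E
    env_idx = np.tile(np.arange(E), L)
    line_idx = np.repeat(np.arange(L), E)

    X_red = np.eye(E)[env_idx]  # (n, E) one-hot
    Q_red, _ = np.linalg.qr(X_red)

    x = 0.5 - G.astype(float)  # A -> +0.5, B -> -0.5
    # (P, I, n): genotype value of each observation's line at each position
    xobs = np.transpose(x[:, line_idx, :], (2, 0, 1))
    Xg = xobs[..., None] * np.eye(E)[env_idx][None, None]  # (P, I, n, E)
    Xfull = np.concatenate(
        [np.broadcast_to(X_red, (P, I, n, E)), Xg], axis=3
    ).reshape(P * I, n, 2 * E)
    mono = (G == G[:, [0], :]).all(axis=1).T.reshape(P * I)  # (P*I,)
    Q, R = np.linalg.qr(Xfull)
    return Q, R, Q_red, mono, env_idx, line_idx


def _combine_lods(lod_pi: np.ndarray, combine: str) -> np.ndarray:
    """Combine per-imputation LODs (axis 1) into one LOD per position."""
    if combine == "mean_likelihood":
        I = lod_pi.shape[1]
        return (logsumexp(lod_pi * LN10, axis=1) - np.log(I)) / LN10
    if combine == "mean_lod":
        return lod_pi.mean(axis=1)
    raise ValueError(f"unknown combine rule {combine!r}")


def _typed_marker_skip(
    imputations: ImputationSet, genotypes_obs: np.ndarray | None, warn: bool = True
):
    """Positions at typed markers where a genotype class has < 2 lines."""
    tab = imputations.grid.table
    skip = np.zeros(len(tab), dtype=bool)
    if genotypes_obs is None:
        return skip
    for t in range(len(tab)):
        obs = genotypes_obs[:, t]
        obs = obs[obs >= 0]
        if len(obs) == 0:
            continue
        nB = int(obs.sum())
        if min(nB, len(obs) - nB) < 2:
            skip[t] = True
            if warn:
                logger.warning(
                    "position %s (%s, %.2f cM) skipped: a genotype class has < 2 lines",
                    tab["marker"].iloc[t],
                    tab["chrom"].iloc[t],
                    tab["cm"].iloc[t],
                )
    return skip


def scan(
    totals: pd.DataFrame,
    imputations: ImputationSet,
    combine: str = "mean_likelihood",
    genotypes: GenotypeMatrix | None = None,
) -> LODProfile:
    """Genome scan: LOD of the full vs reduced model at every grid
    position, combined across imputations; per-environment allele-effect
    estimates (A minus B) averaged across imputations.

    Passing the observed ``genotypes`` enables the typed-marker skip rule
    (positions where an observed genotype class has < 2 lines get NaN).
    """
    Y, envs = _phenotype_matrix(totals, imputations.line_ids)
    y = Y.ravel()
    n = y.size
    E = len(envs)
    I, L, P = imputations.genotypes.shape

    Q, R, Q_red, mono, env_idx, line_idx = _scan_design(imputations, envs)
    yTy = float(y @ y)
    proj_red = Q_red.T @ y
    rss_red = max(yTy - float(proj_red @ proj_red), 1e-300)

    proj = Q.transpose(0, 2, 1) @ y  # (P*I, 2E)
    rss_full = np.maximum(yTy - (proj**2).sum(axis=1), 1e-300)
    rss_full[mono] = rss_red
    lod_pi = (n / 2.0) * np.log10(rss_red / rss_full)
    lod_pi = lod_pi.reshape(P, I)

    # per-imputation effect estimates (allele columns are the last E)
    beta = np.full((P * I, 2 * E), np.nan)
    ok = ~mono
    if ok.any():
        beta[ok] = np.linalg.solve(R[ok], proj[ok, :, None])[..., 0]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-monomorphic slices
        effects = np.nanmean(beta[:, E:].reshape(P, I, E), axis=1)

    ve_pi = 1.0 - (rss_full.reshape(P, I) / rss_red)
    lod = _combine_lods(lod_pi, combine)
    ve = ve_pi.mean(axis=1)

    obs_codes = None
    if genotypes is not None:
        chain = _chain_inputs(genotypes, imputations.grid, "haldane")
        obs_codes = np.full((L, P), -1, dtype=np.int8)
        for _, idx, _, obs in chain:
            obs_codes[:, idx] = obs
    skip = _typed_marker_skip(imputations, obs_codes)
    lod = lod.copy()
    lod[skip] = np.nan
    ve[skip] = np.nan

    tab = imputations.grid.table.copy()
    tab["lod"] = lod
    tab["ve"] = ve
    for e_i, e in enumerate(envs):
        tab[f"effect_{e}"] = effects[:, e_i]
    return LODProfile(tab, envs, I, combine, n)


def permutation_threshold(
    totals: pd.DataFrame,
    imputations: ImputationSet,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    combine: str = "mean_likelihood",
    genotypes: GenotypeMatrix | None = None,
    chunk: int = 200,
) -> tuple[float, np.ndarray]:
    """Genome-wide permutation threshold: permute line identities of the
    phenotype (each line's environment pair moves as a unit), rescan, and
    take the empirical (1-alpha) quantile of the null max LOD."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable quantiles")
    rng = np.random.default_rng(seed)
    Y, envs = _phenotype_matrix(totals, imputations.line_ids)
    L, E = Y.shape
    n = L * E
    I = imputations.genotypes.shape[0]
    P = imputations.grid.n_positions

    Q, R, Q_red, mono, env_idx, line_idx = _scan_design(imputations, envs)
    skip = np.zeros(P, dtype=bool)
    if genotypes is not None:
        chain = _chain_inputs(genotypes, imputations.grid, "haldane")
        obs_codes = np.full((L, P), -1, dtype=np.int8)
        for _, idx, _, obs in chain:
            obs_codes[:, idx] = obs
        skip = _typed_marker_skip(imputations, obs_codes, warn=False)

    max_lods = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(L) for _ in range(m)])
        Yp = Y[perms]  # (m, L, E)
        Ym = Yp.reshape(m, n).T  # (n, m)
        yTy = (Ym**2).sum(axis=0)  # (m,)
        pr = Q_red.T @ Ym  # (E, m)
        rss_red = np.maximum(yTy - (pr**2).sum(axis=0), 1e-300)
        proj = np.einsum("knc,nm->kcm", Q, Ym)
        rss_full = np.maximum(yTy[None, :] - (proj**2).sum(axis=1), 1e-300)
        rss_full[mono] = rss_red[None, :]
        lod = (n / 2.0) * np.log10(rss_red[None, :] / rss_full)
        lod = _combine_lods(lod.reshape(P, I, m), combine)
        lod[skip] = np.nan
        max_lods[done : done + m] = np.nanmax(lod, axis=0)
        done += m
    threshold = float(np.quantile(max_lods, 1.0 - alpha, method="higher"))
    return threshold, max_lods


def variance_explained(profile: LODProfile) -> float:
    """Percent of among-line variance explained at the scan peak:
    mean over imputations of 1 - RSS_full/RSS_reduced, as percent."""
    return float(profile.peak()["ve"] * 100.0)


def lod_support_interval(profile: LODProfile, drop: float = 3.0) -> dict:
    """Maximal contiguous LOD-drop interval around the peak, with the
    typed markers flanking (or at) the interval ends."""
    if drop < 0:
        raise ValueError("drop must be >= 0")
    peak = profile.peak()
    tab = profile.table
    chrom_tab = tab[tab["chrom"] == peak["chrom"]].reset_index(drop=True)
    lods = chrom_tab["lod"].to_numpy(float)
    peak_i = int(np.nanargmax(lods))
    cutoff = lods[peak_i] - drop
    above = ~(lods < cutoff)  # NaN counts as not-below; treat as breaking
    above &= ~np.isnan(lods)
    lo = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(lods) - 1 and above[hi + 1]:
        hi += 1
    markers = chrom_tab["marker"]
    in_window = [m for m in markers.iloc[lo : hi + 1] if m is not None]
    return {
        "chrom": peak["chrom"],
        "peak_cm": float(peak["cm"]),
        "cm_low": float(chrom_tab["cm"].iloc[lo]),
        "cm_high": float(chrom_tab["cm"].iloc[hi]),
        "flank_low": in_window[0] if in_window else None,
        "flank_high": in_window[-1] if in_window else None,
        "drop": float(drop),
    }


def scan_pipeline(
    genotypes: GenotypeMatrix,
    totals: pd.DataFrame,
    n_imputations: int = 50,
    step_cm: float = 3.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    drop: float = 3.0,
    combine: str = "mean_likelihood",
    map_function: str = "haldane",
) -> LODProfile:
    """Convenience wrapper: grid -> imputations -> scan -> threshold."""
    grid = build_grid(genotypes.gmap, step_cm)
    imps = draw_imputations(genotypes, grid, n_imputations, seed, map_function)
    profile = scan(totals, imps, combine, genotypes=genotypes)
    if n_perm:
        thr, null_max = permutation_threshold(
            totals, imps, n_perm, alpha, seed + 1, combine, genotypes
        )
        profile.threshold = thr
        profile.alpha = alpha
        profile.null_max_lod = null_max
    return profile
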