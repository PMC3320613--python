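"""Reference-gene-normalized log2 fold-change inference from qPCR Ct data.

Quantification follows the delta-delta-Ct convention with amplification
efficiency fixed at 2 (perfect doubling): technical replicates are
averaged per biological replicate, each biological replicate's target Ct
is normalized by the reference gene (delta-Ct = Ct_target - Ct_ref), and

    log2FC(group2 vs group1) = mean dCt(group1) - mean dCt(group2),

negative meaning lower expression in group 2.  Inference is
permutation-based: the two-sided p value is the tail proportion of
|log2FC| under reassignment of biological replicates to groups (exact
enumeration when the assignment count is small, Monte-Carlo with
add-one smoothing otherwise).  The reported interval is a percentile
bootstrap over biological replicates, labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeEstimate",
    "collapse_technical",
    "estimate_log2fc",
    "permutation_inference",
]

MAX_EXACT = 20000  # enumerate assignments exactly up to this count


@dataclass
class FoldChangeEstimate:
    """Normalized log2 expression difference of group2 relative to group1."""

    gene: str
    tissue: str | None
    comparison: tuple
    log2_fc: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_permutations: int = 0
    exact: bool = False
    ci_method: str | None = None


def collapse_technical(cts: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct across technical replicates per (sample, group, tissue,
    gene, biological replicate)."""
    keys = ["sample", "group", "tissue", "gene", "bio_rep"]
    return cts.groupby(keys, as_index=False, sort=True)["ct"].mean()


def _delta_ct(cts, target_gene, reference_gene, comparison, tissue):
    df = cts
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    collapsed = collapse_technical(df)
    piv = collapsed.pivot_table(
        index=["group", "bio_rep"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in piv.columns:
            raise ValueError(f"gene {gene!r} missing from Ct table")
    d = {}
    for g in comparison:
        if g not in piv.index.get_level_values("group"):
            raise ValueError(f"group {g!r} missing from Ct table")
        sub = piv.loc[g]
        if sub[reference_gene].isna().any() or sub[target_gene].isna().any():
            raise ValueError(
                f"group {g!r} lacks reference or target Ct for some biological replicate"
            )
        d[g] = (sub[target_gene] - sub[reference_gene]).to_numpy(float)
    return d[comparison[0]], d[comparison[1]]


def estimate_log2fc(
    cts: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "Rpl32",
    comparison: tuple | None = None,
    tissue: str | None = None,
) -> FoldChangeEstimate:
    """Point estimate of the log2 fold change of group2 relative to group1
    (``comparison`` defaults to the two groups in sorted order)."""
    if comparison is None:
        groups = sorted(cts["group"].unique())
        if len(groups) != 2:
            raise ValueError("comparison must be given when groups != 2")
        comparison = tuple(groups)
    d1, d2 = _delta_ct(cts, target_gene, reference_gene, comparison, tissue)
    return FoldChangeEstimate(
        target_gene, tissue, comparison, float(d1.mean() - d2.mean())
    )


def _stat(d1, d2):
    return d1.mean() - d2.mean()


def permutation_inference(
    cts: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "Rpl32",
    comparison: tuple | None = None,
    tissue: str | None = None,
    n_perm: int = 10000,
    n_boot: int = 5000,
    seed: int = 0,
) -> FoldChangeEstimate:
    """Log2 fold change with a permutation p value and bootstrap CI.

    Biological replicates (never technical ones) are the exchangeable
    unit.  With few replicates the permutation null is enumerated
    exactly; otherwise ``n_perm`` Monte-Carlo reassignments are drawn and
    the p value uses add-one smoothing.  The 95% CI is a percentile
    bootstrap over biological replicates (``n_boot`` draws).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if comparison is None:
        groups = sorted(cts["group"].unique())
        if len(groups) != 2:
            raise ValueError("comparison must be given when groups != 2")
        comparison = tuple(groups)
    d1, d2 = _delta_ct(cts, target_gene, reference_gene, comparison, tissue)
    if min(len(d1), len(d2)) < 2:
        raise ValueError("need >= 2 biological replicates per group")
    obs = _stat(d1, d2)
    pooled = np.concatenate([d1, d2])
    n1, ntot = len(d1), len(pooled)
    rng = np.random.default_rng(seed)
    tol = 1e-12

    n_assign = comb(ntot, n1)
    if n_assign <= min(MAX_EXACT, n_perm):
        stats = np.empty(n_assign)
        idx_all = np.arange(ntot)
        for i, pick in enumerate(combinations(idx_all, n1)):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(pick)] = True
            stats[i] = pooled[mask].mean() - pooled[~mask].mean()
        p = float(np.mean(np.abs(stats) >= abs(obs) - tol))
        exact, n_used = True, n_assign
    else:
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ntot)
            s = pooled[perm[:n1]].mean() - pooled[perm[n1:]].mean()
            hits += abs(s) >= abs(obs) - tol
        p = (hits + 1.0) / (n_perm + 1.0)
        exact, n_used = False, n_perm

    b1 = d1[rng.integers(0, len(d1), size=(n_boot, len(d1)))].mean(axis=1)
    b2 = d2[rng.integers(0, len(d2), size=(n_boot, len(d2)))].mean(axis=1)
    lo, hi = np.percentile(b1 - b2, [2.5, 97.5])

    return FoldChangeEstimate(
        target_gene,
        tissue,
        comparison,
        float(obs),
        float(min(lo, obs)),
        float(max(hi, obs)),
        float(p),
        n_used,
        exact,
        "percentile bootstrap over biological replicates",
    )
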