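"""Phenotypic/genetic correlations and variance components for life
history traits (total fecundity, ovariole number, thorax length,
development time).

Standard correlations are pairwise-complete Pearson; partial correlations
come from the precision (inverse correlation) matrix, equivalent to
correlating the residuals after regressing out the remaining traits.
P values are permutation-based (rows of each trait permuted
independently), matching the permutation-first inferential style of the
rest of the package.  Genetic-level analyses operate on line(x
environment) means; variance components (among-line G, line-by-environment
GxE, vial, residual) are REML estimates from a mixed model with
environment fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "line_means",
    "correlation_matrix",
    "partial_correlations",
    "variance_components",
]


def line_means(
    table: pd.DataFrame, traits, by=("line", "environment")
) -> pd.DataFrame:
    """Arithmetic trait means per line x environment cell, with counts."""
    traits = list(traits)
    g = table.groupby(list(by), as_index=False, sort=True)
    out = g[traits].mean()
    out["n"] = g.size()["size"].to_numpy()
    return out


def partial_correlations(corr: np.ndarray) -> np.ndarray:
    """Partial correlation matrix from a full correlation matrix via the
    precision matrix: r_ij = -P_ij / sqrt(P_ii P_jj)."""
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise ValueError("singular correlation matrix; cannot form partials") from None
    d = np.sqrt(np.diag(prec))
    out = -prec / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _corr(X: np.ndarray, method: str) -> np.ndarray:
    df = pd.DataFrame(X)
    r = df.corr(min_periods=2).to_numpy()
    if method == "partial":
        if np.isnan(r).any():
            raise ValueError("missing pairwise correlations; cannot form partials")
        r = partial_correlations(r)
    return r


def correlation_matrix(
    table: pd.DataFrame,
    traits,
    method: str = "standard",
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait correlation matrix with permutation p values.

    method='standard': pairwise-complete Pearson.  method='partial':
    each pair conditioned on all remaining traits (complete-case).
    Returns (correlations, p_values) as DataFrames.
    """
    if method not in ("standard", "partial"):
        raise ValueError(f"unknown method {method!r}")
    traits = list(traits)
    X = table[traits].to_numpy(float)
    if method == "partial":
        X = X[~np.isnan(X).any(axis=1)]
        if len(X) < len(traits) + 1:
            raise ValueError("too few complete rows for partial correlations")
    r_obs = _corr(X, method)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(r_obs)
    for _ in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        rp = _corr(Xp, method)
        exceed += np.abs(rp) >= np.abs(r_obs) - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)
    np.fill_diagonal(p, np.nan)
    rdf = pd.DataFrame(r_obs, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    return rdf, pdf


def variance_components(
    table: pd.DataFrame,
    response: str,
    line: str = "line",
    environment: str = "environment",
    vial: str | None = "vial",
    lrt: bool = True,
) -> dict:
    """REML variance decomposition: environment fixed; line (G),
    line-by-environment (GxE) and optionally vial random.

    Returns the components, the broad-sense fraction
    V_line / (V_line + V_GxE + V_vial + V_resid), and (optionally)
    conservative chi-square(2) LRT p values for dropping each random term
    (refit by ML).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = table.dropna(subset=[response]).copy()
    if df[line].nunique() < 2 or df[environment].nunique() < 2:
        raise ValueError("need >= 2 lines and >= 2 environments")
    counts = df.groupby([line, environment]).size()
    if (counts < 2).all():
        raise ValueError("unreplicated design: no line x environment cell has replicates")

    df["_le"] = df[line].astype(str) + ":" + df[environment].astype(str)
    vc = {"line_env": f"0 + C(_le)"}
    if vial is not None and vial in df.columns:
        df["_vial"] = df[vial].astype(str)
        vc["vial"] = "0 + C(_vial)"

    def _fit(vc_formula, reml=True):
        model = MixedLM.from_formula(
            f"{response} ~ C({environment})",
            groups=line,
            vc_formula=vc_formula,
            re_formula="1",
            data=df,
        )
        return model.fit(reml=reml, method=["lbfgs", "powell"])

    res = _fit(vc)
    comps = {"line": float(np.asarray(res.cov_re)[0, 0])}
    for i, name in enumerate(vc):
        comps[name] = float(res.vcomp[i])
    comps["residual"] = float(res.scale)
    total = sum(comps.values())
    out = {
        "components": comps,
        "broad_sense": comps["line"] / total if total > 0 else np.nan,
        "reml_loglik": float(res.llf),
    }
    if lrt:
        full_ml = _fit(vc, reml=False).llf
        pvals = {}
        # drop the line random intercept (keep vc terms)
        no_line = MixedLM.from_formula(
            f"{response} ~ C({environment})",
            groups=line,
            vc_formula=vc,
            re_formula="0",
            data=df,
        ).fit(reml=False, method=["lbfgs", "powell"])
        stat = max(2.0 * (full_ml - no_line.llf), 0.0)
        pvals["line"] = float(chi2.sf(stat, 2))
        for name in vc:
            rest = {k: v for k, v in vc.items() if k != name}
            kwargs = {"vc_formula": rest} if rest else {}
            red = MixedLM.from_formula(
                f"{response} ~ C({environment})",
                groups=line,
                re_formula="1",
                data=df,
                **kwargs,
            ).fit(reml=False, method=["lbfgs", "powell"])
            stat = max(2.0 * (full_ml - red.llf), 0.0)
            pvals[name] = float(chi2.sf(stat, 2))
        out["lrt_pvalues"] = pvals
    return out
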