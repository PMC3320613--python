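"""Quantitative-complementation and RNAi contrast tests.

A deficiency fails to complement the two natural alleles when fecundity
satisfies the a-priori contrast

    (A/Bal) = (B/Bal) = (A/Def) > (B/Def),

where A and B are the high- and low-fecundity RIL alleles, Bal the
balancer tester and Def the deficiency.  The machinery fits the
linearized fecundity curve with contrast terms shifting the transformed
intercept (plus declared random effects: RIL, and vial nested within
RIL), then performs sequential likelihood-ratio tests that remove the
contrast terms last-to-first, refitting by maximum likelihood.  Each LRT
statistic is referred to a chi-square distribution with TWO degrees of
freedom even though a single parameter is removed: fixed-effect LRTs in
mixed models are anticonservative against chi-square(1), and the 2-df
reference makes the test deliberately conservative.

A deficiency is called *fails_to_complement* iff any sequential LRT is
significant AND the corresponding contrast estimate is negative.  RNAi
designs (control vs knock-down) run the same engine with a single
treatment contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .fecundity import (
    bootstrap_total_fecundity,
    fit_fecundity_curve,
    integrate_total_fecundity,
    transform_counts,
)

__all__ = [
    "ContrastDesign",
    "ContrastTestResult",
    "default_complementation_design",
    "default_rnai_design",
    "conservative_lrt_pvalue",
    "fit_contrast_model",
    "classify_complementation",
]

CONSERVATIVE_DF = 2


@dataclass(frozen=True)
class ContrastDesign:
    """Ordered genotype classes and the ordered contrast vectors over them.

    Contrasts are tested sequentially: the LAST contrast is removed first.
    """

    classes: tuple
    contrasts: tuple  # of (name, vector) pairs
    random: tuple | None = ("line", "vial")
    alpha: float = 0.05
    calls: tuple = ("fails_to_complement", "complements")

    def __post_init__(self):
        if len(self.classes) < 2:
            raise ValueError("need at least 2 genotype classes")
        for name, vec in self.contrasts:
            if len(vec) != len(self.classes):
                raise ValueError(
                    f"contrast {name!r} has length {len(vec)}, "
                    f"expected {len(self.classes)}"
                )
            if not any(v != 0 for v in vec):
                raise ValueError(f"contrast {name!r} is all-zero")


def default_complementation_design(
    classes=("A/Bal", "B/Bal", "A/Def", "B/Def"),
) -> ContrastDesign:
    """A = indicator of A/Def, B = indicator of B/Def; B is removed first."""
    return ContrastDesign(
        classes=tuple(classes),
        contrasts=(("A", (0, 0, 1, 0)), ("B", (0, 0, 0, 1))),
    )


def default_rnai_design(classes=("control", "RNAi")) -> ContrastDesign:
    """Single treatment contrast [0, 1] = [control, RNAi].

    The two arms are genetically uniform crosses, so the random structure
    is the rearing vial (no RIL level)."""
    return ContrastDesign(
        classes=tuple(classes),
        contrasts=(("treatment", (0, 1)),),
        random=("vial",),
        calls=("rnai_reduces", "no_effect"),
    )


def conservative_lrt_pvalue(stat: float, df: int = CONSERVATIVE_DF) -> float:
    """Upper tail of chi-square(df); df=2 by convention even for 1-parameter
    removals (deliberately conservative)."""
    if stat < -1e-8:
        raise ValueError(f"negative LRT statistic: {stat}")
    return float(chi2.sf(max(stat, 0.0), df))


@dataclass
class ContrastTestResult:
    """Sequential LRT outcomes, contrast estimates and the resulting call."""

    contrasts: pd.DataFrame  # name, estimate, lrt, p_value
    logliks: list
    class_totals: dict
    design: ContrastDesign = field(repr=False)
    alpha: float = 0.05
    call: str | None = None


def _contrast_columns(classes, contrasts, class_of_row):
    idx = {c: i for i, c in enumerate(classes)}
    pos = np.array([idx[c] for c in class_of_row])
    cols = []
    for name, vec in contrasts:
        v = np.asarray(vec, dtype=float)
        cols.append(v[pos])
    return cols


def _ml_loglik_ols(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    # variance floored well above float noise so exact-fit (zero-residual)
    # data yields identical logliks for all nested models
    s2 = max(float(resid @ resid) / n, 1e-10)
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0), beta


def _ml_loglik_mixed(df, contrast_cols, random):
    """ML fit of the curve + contrast model with random intercepts for
    ``random[0]`` and (optionally) ``random[1]`` nested within it."""
    import warnings

    from statsmodels.regression.mixed_linear_model import MixedLM

    rhs = "1 + log_age + age" + "".join(f" + {c}" for c in contrast_cols)
    kwargs = {}
    if len(random) > 1:
        kwargs["vc_formula"] = {random[1]: f"0 + C({random[1]})"}
    with warnings.catch_warnings():
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model = MixedLM.from_formula(
            f"y ~ {rhs}", groups=random[0], re_formula="1", data=df, **kwargs
        )
        res = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                cand = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue  # singular Hessian: variance component on boundary
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
    if res is not None:
        fe = res.fe_params
        beta = np.concatenate(
            [
                [fe["Intercept"], fe["log_age"], fe["age"]],
                [fe[c] for c in contrast_cols],
            ]
        )
        return float(res.llf), beta
    # all random variances on the zero boundary: the constrained ML optimum
    # is ordinary least squares, whose Gaussian loglik we report
    return _ml_loglik_ols(np.asarray(model.exog), np.asarray(model.endog))


def fit_contrast_model(
    records: pd.DataFrame,
    design: ContrastDesign,
    n_boot: int = 1000,
    seed: int = 0,
    shape_contrasts: bool = False,
) -> ContrastTestResult:
    """Fit the contrast model and run the sequential likelihood-ratio tests.

    The full model is the linearized fecundity curve (shared shape) with
    one intercept-shift term per contrast; reduced models drop contrasts
    from the end of the ordered list.  All fits use maximum likelihood.
    With ``shape_contrasts`` the contrasts also act on the curve's shape
    coefficients (sensitivity analysis).
    """
    present = set(records["genotype_class"].unique())
    missing = [c for c in design.classes if c not in present]
    if missing:
        raise ValueError(f"genotype classes missing from data: {missing}")

    df = transform_counts(records[records["genotype_class"].isin(design.classes)])
    y = df["y"].to_numpy(float)
    base = np.column_stack(
        [np.ones(len(df)), df["log_age"].to_numpy(), df["age"].to_numpy()]
    )
    ccols = _contrast_columns(design.classes, design.contrasts, df["genotype_class"])
    if shape_contrasts:
        expanded = []
        for c in ccols:
            expanded.extend([c, c * df["log_age"].to_numpy(), c * df["age"].to_numpy()])
        ccols = expanded
    per_contrast = 3 if shape_contrasts else 1
    names = []
    for i, c in enumerate(ccols):
        name = f"_c{i}"
        df[name] = c
        names.append(name)

    random = design.random
    k = len(design.contrasts)
    logliks = []
    full_beta = None
    for j in range(k + 1):
        if random is None:
            X = np.column_stack([base] + ccols[: j * per_contrast]) if j else base
            ll, beta = _ml_loglik_ols(X, y)
        else:
            ll, beta = _ml_loglik_mixed(df, names[: j * per_contrast], random)
        logliks.append(ll)
        if j == k:
            full_beta = beta

    rows = []
    for j, (name, _) in enumerate(design.contrasts):
        # clamp at 0: a nested fit ending on a variance boundary can give
        # a marginally higher loglik than the fuller model
        lrt = max(2.0 * (logliks[j + 1] - logliks[j]), 0.0)
        est = float(full_beta[3 + j * per_contrast])
        rows.append((name, est, lrt, conservative_lrt_pvalue(lrt)))
    contrast_df = pd.DataFrame(rows, columns=["name", "estimate", "lrt", "p_value"])

    if n_boot > 0:
        class_totals = bootstrap_total_fecundity(
            records, strata="genotype_class", n_boot=n_boot, seed=seed
        )
    else:
        fit = fit_fecundity_curve(records, strata=("genotype_class",), random=None)
        class_totals = {
            c: integrate_total_fecundity(fit, c) for c in design.classes
        }

    result = ContrastTestResult(
        contrast_df, logliks, class_totals, design, design.alpha
    )
    result.call = classify_complementation(result, design.alpha)
    return result


def classify_complementation(result: ContrastTestResult, alpha: float = 0.05) -> str:
    """Failure to complement (or RNAi effect) iff any sequential LRT is
    significant at ``alpha`` AND that contrast's estimate is negative."""
    fail, ok = result.design.calls
    hit = (result.contrasts["p_value"] < alpha) & (result.contrasts["estimate"] < 0)
    return fail if bool(hit.any()) else ok
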