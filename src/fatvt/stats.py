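"""Cohort statistics: the battery of tests used throughout the analysis.

Unbalanced one-way ANOVA, Fisher's exact odds ratios, multivariable
Poisson regression with per-increment rate ratios, covariate-adjusted
linear regression, Pearson correlation and unpaired t-tests.  All tests
are two-sided and no multiple-testing correction is applied (raw
p-values are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "anova_unbalanced",
    "fisher_or",
    "poisson_regression",
    "linear_regression_adjusted",
    "pearson_r",
    "unpaired_t",
]


@dataclass
class RegressionResult:
    """Coefficients with inference, plus per-increment rate ratios (Poisson)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    rate_ratios: pd.Series | None = None        # exp(beta * increment)
    increment: float | None = None
    percent_per_increment: pd.Series | None = None  # 100*(exp(beta*inc) - 1)
    model: object = field(default=None, repr=False)


def anova_unbalanced(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p for (possibly unequal-sized) groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 0.0, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def fisher_or(
    table, ci_method: str = "conditional", alpha: float = 0.05
) -> dict:
    """Fisher's exact test on a 2x2 table.

    Returns the sample odds ratio ad/bc, the exact (two-sided) p-value,
    and a confidence interval.  ``ci_method='conditional'`` uses the
    conditional maximum-likelihood (exact) interval; ``'logit'`` the
    normal approximation on the log odds ratio.  A zero margin flags the
    odds ratio as undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = t.ravel()
    undefined = (b * c) == 0
    sample_or = np.inf if undefined and a * d > 0 else (
        np.nan if undefined else (a * d) / (b * c)
    )
    _, p = sps.fisher_exact(t, alternative="two-sided")
    if ci_method == "conditional":
        res = sps.contingency.odds_ratio(t.astype(int), kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        lo, hi = float(ci.low), float(ci.high)
    elif ci_method == "logit":
        with np.errstate(divide="ignore"):
            se = np.sqrt((1 / np.maximum(t, 1e-300)).sum())
            log_or = np.log(sample_or) if np.isfinite(sample_or) and sample_or > 0 else np.nan
        z = sps.norm.ppf(1 - alpha / 2)
        lo, hi = float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "odds_ratio": float(sample_or) if np.isfinite(sample_or) else sample_or,
        "p": float(p),
        "ci": (lo, hi),
        "ci_method": ci_method,
        "undefined": bool(undefined),
    }


def poisson_regression(
    counts,
    predictors: pd.DataFrame,
    increment_g: float = 5.55,
    max_iter: int = 200,
) -> RegressionResult:
    """Log-link Poisson GLM of event counts on predictors (IRLS fit).

    Rate ratios are reported per ``increment_g`` units of each predictor:
    exp(beta * increment), with the corresponding percent change
    100*(exp(beta*increment) - 1).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    X = sm.add_constant(pd.DataFrame(predictors), has_constant="add")
    if np.linalg.matrix_rank(np.asarray(X, dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    fit = model.fit(maxiter=max_iter)
    if not fit.converged:
        raise RuntimeError("Poisson IRLS did not converge")
    rr = np.exp(fit.params * increment_g)
    return RegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        conf_int=fit.conf_int(),
        rate_ratios=rr, increment=increment_g,
        percent_per_increment=100.0 * (rr - 1.0),
        model=fit,
    )


def linear_regression_adjusted(
    y,
    exposure,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
) -> RegressionResult:
    """OLS of ``y`` on an exposure, adjusted for covariates.

    The exposure coefficient (name ``exposure_name``) carries the
    adjusted association of interest.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame({exposure_name: np.asarray(exposure, dtype=float)})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of parameters")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(np.asarray(X, dtype=float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        conf_int=fit.conf_int(), model=fit,
    )


def pearson_r(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def unpaired_t(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("zero variance")
    t, p = sps.ttest_ind(a, b)
    return float(t), float(p)
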