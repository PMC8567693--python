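"""Standardized regression battery, multiple-testing control, linear-vs-
quadratic model choice and the noncentral-F sample-size calculation.

All analysis variables are z-scaled before entering a model, so a simple
regression estimate equals the Pearson correlation and coefficients are
comparable across phenotypes.  Model choice between ``y ~ x`` and
``y ~ x + x^2`` is by AIC with residual diagnostics logged alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("placentamed")


@dataclass(frozen=True)
class RegressionResult:
    estimate: float
    ci95: tuple[float, float]
    p_value: float
    adjusted_r2: float
    n: int
    p_bonferroni: float | None = None


def regress(
    outcome: np.ndarray,
    predictor: np.ndarray,
    confounders: np.ndarray | None = None,
    family_size: int = 1,
) -> RegressionResult:
    """OLS of outcome on predictor (plus confounder columns), complete cases.

    Returns the predictor's coefficient with a t-based 95% CI, two-sided p,
    adjusted R^2 and, when ``family_size`` > 1, the Bonferroni-adjusted p.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cols = [x]
    if confounders is not None:
        c = np.asarray(confounders, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols.extend(c.T)
    X = np.column_stack(cols)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    n, k = X.shape
    if n < k + 3:  # parameters = k slopes + intercept; need at least 2 residual df
        raise ValueError(f"n = {n} too small for {k + 1} parameters")
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)[1]
    p = float(model.pvalues[1])
    return RegressionResult(
        estimate=float(model.params[1]),
        ci95=(float(ci[0]), float(ci[1])),
        p_value=p,
        adjusted_r2=float(model.rsquared_adj),
        n=n,
        p_bonferroni=min(1.0, p * family_size) if family_size > 1 else None,
    )


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


@dataclass(frozen=True)
class ModelChoice:
    preferred: str                 # "linear" | "quadratic"
    aic_linear: float
    aic_quadratic: float
    quadratic_p: float             # Wald p of the squared term
    residual_normality_p: float    # Shapiro-Wilk on preferred-model residuals


def compare_linear_quadratic(outcome: np.ndarray, predictor: np.ndarray) -> ModelChoice:
    """Fit y ~ x and y ~ x + x^2; prefer the lower-AIC model and log residual
    diagnostics for the preferred fit."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    if y.size < 10:
        raise ValueError("model comparison needs n >= 10")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    lin = sm.OLS(y, sm.add_constant(x)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x ** 2]))).fit()
    preferred = "linear" if lin.aic <= quad.aic else "quadratic"
    resid = (lin if preferred == "linear" else quad).resid
    sw_p = float(stats.shapiro(resid).pvalue) if resid.size <= 5000 else np.nan
    choice = ModelChoice(
        preferred=preferred,
        aic_linear=float(lin.aic),
        aic_quadratic=float(quad.aic),
        quadratic_p=float(quad.pvalues[2]),
        residual_normality_p=sw_p,
    )
    logger.info(
        "model choice: %s (AIC %.2f vs %.2f), residual normality p=%.3g",
        choice.preferred, choice.aic_linear, choice.aic_quadratic, sw_p,
    )
    return choice


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the regression power calculation.

    ``f2`` is Cohen's effect size; by convention f2 = R^2/(1 - R^2), though
    some analysts pass R^2 directly — both are supported downstream.
    """

    alpha: float = 0.05
    power: float = 0.80
    r2: float = 0.15
    u: int = 1  # numerator degrees of freedom (number of tested predictors)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1 and 0 < self.r2 < 1):
            raise ValueError("alpha, power and r2 must all lie in (0, 1)")
        if self.u < 1:
            raise ValueError("u must be >= 1")

    def f2(self, convention: str = "f2_from_r2") -> float:
        if convention == "f2_from_r2":
            return self.r2 / (1 - self.r2)
        if convention == "f2_is_r2":
            return self.r2
        raise ValueError(f"unknown f2 convention {convention!r}")


def achieved_power(n: int, spec: PowerSpec, convention: str = "f2_from_r2") -> float:
    """Power of the overall regression F test at sample size n.

    Noncentral-F with numerator df u, denominator df v = n - u - 1 and
    noncentrality f2 * (u + v + 1) = f2 * n.
    """
    v = n - spec.u - 1
    if v < 1:
        return 0.0
    f2 = spec.f2(convention)
    lam = f2 * (spec.u + v + 1)
    crit = stats.f.isf(spec.alpha, spec.u, v)
    return float(stats.ncf.sf(crit, spec.u, v, lam))


def required_sample_size(spec: PowerSpec, convention: str = "f2_from_r2", n_max: int = 100_000) -> int:
    """Smallest n whose achieved power meets the target (power is monotone in
    n, so a bracketing bisection is exact)."""
    lo, hi = spec.u + 2, None
    if achieved_power(lo, spec, convention) >= spec.power:
        return lo
    n = lo
    while n < n_max:
        n = min(2 * n, n_max)
        if achieved_power(n, spec, convention) >= spec.power:
            hi = n
            break
    if hi is None:
        raise ValueError("target power unreachable below n_max; infeasible spec")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieved_power(mid, spec, convention) >= spec.power:
            hi = mid
        else:
            lo = mid
    return hi


def sample_size_conventions(spec: PowerSpec) -> dict[str, int]:
    """Minimum n under each documented f2 convention."""
    return {c: required_sample_size(spec, c) for c in ("f2_from_r2", "f2_is_r2")}
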