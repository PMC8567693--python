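"""Linear-model causal mediation with quasi-Bayesian Monte Carlo intervals
and a sensitivity analysis for sequential ignorability.

Two OLS fits define the mediation system (confounders C enter both):

    mediator model:  M = a0 + a·X + g_m·C + e_m
    outcome model:   Y = b0 + c'·X + b·M + g_y·C + e_y

With linear models and no exposure–mediator interaction the average causal
mediation effect (ACME) is a·b, the average direct effect (ADE) is c', and
ACME + ADE equals the total effect exactly.  Uncertainty is quantified by
drawing coefficient vectors from the asymptotic multivariate normal of each
fit and propagating them through the effect formulas (quasi-Bayesian Monte
Carlo); intervals are percentile-based.

Sequential ignorability — no unmeasured confounding of the mediator–outcome
relation — is probed by the sensitivity parameter rho, the correlation
between the mediator-model and outcome-model errors.  For the linear
structural equation system the ACME at a given rho has the closed form

    ACME(rho) = (a·s1/s2) · [ r~ − rho·sqrt((1 − r~²)/(1 − rho²)) ]

where s1, s2 are the residual SDs of the total-effect outcome model
(Y ~ X + C) and the mediator model, and r~ is the correlation between those
two residual series; ACME(0) reproduces the baseline a·b estimate and the
curve crosses zero at rho = r~.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

EFFECTS = ("acme", "ade", "total", "prop_mediated")


@dataclass
class MediationResult:
    """Point estimates (from the fitted coefficients), percentile CIs and
    two-sided Monte Carlo p-values for ACME, ADE, total effect and the
    proportion mediated."""

    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci: dict                    # effect -> (low, high)
    p_value: dict               # effect -> float
    p_resolution_limited: dict  # effect -> True when no draw crossed zero
    n_sims: int
    seed: int
    n_prop_excluded: int        # draws dropped from the proportion CI (|total| ~ 0)
    # retained data for the sensitivity analysis
    _X: np.ndarray = field(repr=False, default=None)
    _M: np.ndarray = field(repr=False, default=None)
    _Y: np.ndarray = field(repr=False, default=None)
    _C: np.ndarray | None = field(repr=False, default=None)


def _design(x: np.ndarray, *extra: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(x), x, *extra]
    return np.column_stack(cols)


def mediate(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    confounders: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Quasi-Bayesian causal mediation for continuous mediator and outcome.

    All variables should be z-scaled.  Per-draw proportion-mediated ratios
    with |total| below machine resolution are excluded from the proportion
    CI and tallied, since the ratio is unstable near a null total effect.
    """
    if n_sims < 100:
        warnings.warn("n_sims < 100 gives unstable Monte Carlo intervals")
    X = np.asarray(exposure, dtype=float)
    M = np.asarray(mediator, dtype=float)
    Y = np.asarray(outcome, dtype=float)
    C = None
    conf_cols: tuple[np.ndarray, ...] = ()
    if confounders is not None:
        C = np.asarray(confounders, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        conf_cols = tuple(C.T)

    Xm = _design(X, *conf_cols)
    Xy = _design(X, M, *conf_cols)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1] or np.linalg.matrix_rank(Xy) < Xy.shape[1]:
        raise ValueError("collinear design matrix")
    med_fit = sm.OLS(M, Xm).fit()
    out_fit = sm.OLS(Y, Xy).fit()

    a_hat = med_fit.params[1]
    b_hat = out_fit.params[2]
    c_hat = out_fit.params[1]
    acme, ade = float(a_hat * b_hat), float(c_hat)
    total = acme + ade
    prop = acme / total if total != 0 else np.nan

    rng = np.random.default_rng(seed)
    med_draws = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_sims)
    out_draws = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), size=n_sims)
    acme_d = med_draws[:, 1] * out_draws[:, 2]
    ade_d = out_draws[:, 1]
    total_d = acme_d + ade_d

    stable = np.abs(total_d) > 1e-10
    prop_d = np.where(stable, acme_d / np.where(stable, total_d, 1.0), np.nan)
    n_excluded = int((~stable).sum())

    draws = {"acme": acme_d, "ade": ade_d, "total": total_d, "prop_mediated": prop_d[stable]}
    ci, pvals, limited = {}, {}, {}
    for name, d in draws.items():
        ci[name] = tuple(np.percentile(d, [2.5, 97.5]))
        if name == "prop_mediated":
            continue
        frac_le = (d <= 0).mean()
        frac_ge = (d >= 0).mean()
        p = 2 * min(frac_le, frac_ge)
        limited[name] = p == 0
        pvals[name] = max(p, 2 / n_sims) if p == 0 else min(p, 1.0)

    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=float(prop),
        ci=ci, p_value=pvals, p_resolution_limited=limited,
        n_sims=n_sims, seed=seed, n_prop_excluded=n_excluded,
        _X=X, _M=M, _Y=Y, _C=C,
    )


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class SensitivityCurve:
    rho_grid: np.ndarray
    acme_at_rho: np.ndarray
    rho_zero_crossing: float | None  # residual correlation r~, if inside the grid

    def at(self, rho: float) -> float:
        i = int(np.argmin(np.abs(self.rho_grid - rho)))
        if abs(self.rho_grid[i] - rho) > 1e-9:
            raise KeyError(f"rho {rho} not on grid")
        return float(self.acme_at_rho[i])


def sensitivity(result: MediationResult, rho_grid: np.ndarray | None = None) -> SensitivityCurve:
    """ACME as a function of the mediator/outcome residual correlation rho,
    from the closed-form linear-SEM expression; requires |rho| < 1."""
    rho_grid = np.round(np.arange(-0.9, 0.91, 0.1), 10) if rho_grid is None else np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 1):
        raise ValueError("|rho| must be < 1")
    X, M, Y, C = result._X, result._M, result._Y, result._C
    conf_cols = () if C is None else tuple(C.T)

    med_fit = sm.OLS(M, _design(X, *conf_cols)).fit()
    tot_fit = sm.OLS(Y, _design(X, *conf_cols)).fit()  # total-effect outcome model
    a_hat = med_fit.params[1]
    e2, e1 = med_fit.resid, tot_fit.resid
    s1, s2 = e1.std(ddof=0), e2.std(ddof=0)
    r_tilde = float(np.corrcoef(e1, e2)[0, 1])

    acme_rho = (a_hat * s1 / s2) * (
        r_tilde - rho_grid * np.sqrt((1 - r_tilde ** 2) / (1 - rho_grid ** 2))
    )
    crossing = r_tilde if rho_grid.min() <= r_tilde <= rho_grid.max() else None
    return SensitivityCurve(rho_grid, acme_rho, crossing)


# ---------------------------------------------------------------------------
# battery over exposure definitions
# ---------------------------------------------------------------------------


def mediation_battery(
    exposures: Mapping[str, np.ndarray],
    mediator: np.ndarray,
    outcome: np.ndarray,
    confounders: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One mediation fit per exposure definition (full score, pleiotropy-
    excluded scores, vasculature-class subscores), sharing mediator, outcome
    and confounders; rows in input order."""
    rows = []
    for i, (name, x) in enumerate(exposures.items()):
        r = mediate(x, mediator, outcome, confounders, n_sims=n_sims, seed=seed + i)
        rows.append(
            {
                "exposure": name,
                "acme": r.acme, "acme_lo": r.ci["acme"][0], "acme_hi": r.ci["acme"][1],
                "acme_p": r.p_value["acme"],
                "ade": r.ade, "ade_p": r.p_value["ade"],
                "total": r.total, "total_p": r.p_value["total"],
                "prop_mediated": r.prop_mediated,
                "prop_lo": r.ci["prop_mediated"][0], "prop_hi": r.ci["prop_mediated"][1],
            }
        )
    return pd.DataFrame(rows).set_index("exposure")
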