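"""Fetal growth curves and gestational-week-specific velocity.

Each fetus's serial estimated-fetal-weight (EFW) observations are fit with a
cubic smoothing spline whose penalty is chosen by generalized
cross-validation; weekly EFW is read off an interior integer-week grid (no
extrapolation) and weekly velocity is the first difference — the increment
ending at week w.  Velocities are z-normalized cross-sectionally per week,
participants are stratified by polygenic-score tertile, and velocity is
regressed on the tertile stratum (coded 1–3) every two weeks from 22 to 36
with Bonferroni control over the 8 tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from . import association
from .phenotype import DegenerateInputWarning

logger = logging.getLogger("placentamed")

DEFAULT_REGRESSION_WEEKS = tuple(range(22, 37, 2))


@dataclass
class GrowthCurve:
    """Weekly EFW (g) and velocity (g/week) on the interior integer grid."""

    pair_id: str
    weeks: np.ndarray          # ceil(first obs) .. floor(last obs)
    efw_weekly: np.ndarray
    velocity: np.ndarray       # velocity[i] is the increment ending at weeks[i+1]
    smoothing: str = "gcv"

    def velocity_at(self, week: int) -> float | None:
        """Velocity of the increment ending at ``week``; None off-grid."""
        if week <= self.weeks[0] or week > self.weeks[-1]:
            return None
        return float(self.velocity[int(week - self.weeks[0]) - 1])


def fit_growth_curve(
    pair_id: str,
    observations: list[tuple[float, float]],
    min_obs: int = 4,
    min_span: float = 6.0,
) -> GrowthCurve | None:
    """GCV-penalized cubic smoothing spline through one fetus's EFW series.

    Returns None (with a logged reason) for series with fewer than
    ``min_obs`` observations or spanning less than ``min_span`` weeks.
    """
    if len(observations) < min_obs:
        logger.info("%s excluded: %d < %d observations", pair_id, len(observations), min_obs)
        return None
    weeks = np.array([w for w, _ in observations], dtype=float)
    efw = np.array([e for _, e in observations], dtype=float)
    if np.any(np.diff(weeks) <= 0):
        raise ValueError(f"{pair_id}: observation weeks must be strictly increasing")
    if weeks[-1] - weeks[0] < min_span:
        logger.info("%s excluded: span %.1f < %.1f weeks", pair_id, weeks[-1] - weeks[0], min_span)
        return None

    if len(weeks) >= 5:
        spline = make_smoothing_spline(weeks, efw)  # lam chosen by GCV
    else:
        # exactly min_obs=4 points: the lam->0 limit of the smoothing spline
        # is the interpolating natural cubic spline
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(weeks, efw, bc_type="natural")
    grid = np.arange(math.ceil(weeks[0]), math.floor(weeks[-1]) + 1, dtype=float)
    if grid.size < 2:
        logger.info("%s excluded: interior grid shorter than 2 weeks", pair_id)
        return None
    weekly = spline(grid)
    return GrowthCurve(pair_id, grid.astype(int), weekly, np.diff(weekly))


def weekly_velocity_table(curves: list[GrowthCurve]) -> pd.DataFrame:
    """Long-to-wide velocity matrix: rows weeks, columns fetuses, NaN where a
    fetus's grid does not cover the week."""
    series = {
        c.pair_id: pd.Series(c.velocity, index=c.weeks[1:].astype(int))
        for c in curves
    }
    return pd.DataFrame(series).sort_index()


def weekly_znorm(curves: list[GrowthCurve], week: int) -> pd.Series:
    """Cross-sectional z-scores of velocity at one week.

    Fetuses whose grid lacks the week are missing (not zero); a week with
    fewer than 2 fetuses raises; identical velocities are flagged degenerate
    and returned as zeros.
    """
    vals = {}
    for c in curves:
        v = c.velocity_at(week)
        if v is not None:
            vals[c.pair_id] = v
    if len(vals) < 2:
        raise ValueError(f"week {week}: fewer than 2 fetuses with velocity on grid")
    s = pd.Series(vals)
    sd = s.std(ddof=1)
    if sd == 0:
        warnings.warn(f"week {week}: identical velocities", DegenerateInputWarning)
        return s * 0.0
    return (s - s.mean()) / sd


def tertile_stratify(scores: pd.Series) -> pd.Series:
    """Stratum 1/2/3 at the empirical 1/3 and 2/3 quantiles; ties go to the
    lower stratum.  Invariant under monotone transformation of the scores."""
    if scores.size < 3:
        raise ValueError("tertile stratification needs at least 3 samples")
    if scores.nunique() == 1:
        raise ValueError("constant scores cannot be stratified")
    q1, q2 = np.quantile(scores.to_numpy(dtype=float), [1 / 3, 2 / 3])
    return pd.Series(1 + (scores > q1).astype(int) + (scores > q2).astype(int), index=scores.index)


def velocity_regressions(
    curves: list[GrowthCurve],
    strata: pd.Series,
    weeks: tuple[int, ...] = DEFAULT_REGRESSION_WEEKS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-week OLS of z-normalized velocity on the tertile stratum (numeric
    1–3, so the estimate is the change per stratum increase), flagged at the
    Bonferroni threshold for the family of tests."""
    thr = association.bonferroni(alpha, len(weeks))
    rows = []
    for week in weeks:
        z = weekly_znorm(curves, week)
        common = z.index.intersection(strata.index)
        res = association.regress(
            z.loc[common].to_numpy(), strata.loc[common].to_numpy(dtype=float)
        )
        rows.append(
            {
                "week": week,
                "estimate": res.estimate,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "p_value": res.p_value,
                "n": res.n,
                "significant": res.p_value < thr,
            }
        )
    out = pd.DataFrame(rows).set_index("week")
    out.attrs["bonferroni_threshold"] = thr
    return out
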