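"""Derived blood-pressure phenotypes, eligibility filtering, reference-chart
standardization and z-scaling.

Pulse pressure is SBP − DBP; mean arterial pressure is DBP + PP/3.  BP
observations are averaged within three gestation periods — early (< 20 w),
middle (20 ≤ w < 34) and late (≥ 34 w) — matching the clinical onset
categories of hypertensive disorders of pregnancy.  Birth and placental
weight are standardized against a reference chart stratified by completed
gestational week, fetal sex and parity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import ChartCoverageError, PhenotypeRecord, ReferenceChart

PERIODS = ("early", "middle", "late")
BP_TRAITS = ("sbp", "dbp", "pp", "map")


class DegenerateInputWarning(UserWarning):
    pass


def _period(week: float) -> str:
    if week < 20:
        return "early"
    if week < 34:
        return "middle"
    return "late"


@dataclass(frozen=True)
class DerivedBP:
    """Per-observation PP/MAP plus per-period means.

    ``period_means[(period, trait)]`` is NaN when the record has no
    observation in that period; ``missing_periods`` lists them so callers can
    exclude the record from analyses needing that period.
    """

    pair_id: str
    observations: tuple  # (week, sbp, dbp, pp, map)
    period_means: dict
    missing_periods: tuple


def derive_bp(record: PhenotypeRecord) -> DerivedBP:
    if not record.bp_obs:
        raise ValueError(f"{record.pair_id}: no BP observations")
    obs = []
    by_period: dict[str, list[tuple[float, float, float, float]]] = {p: [] for p in PERIODS}
    for week, sbp, dbp in record.bp_obs:
        pp = sbp - dbp
        map_ = dbp + pp / 3.0
        obs.append((week, sbp, dbp, pp, map_))
        by_period[_period(week)].append((sbp, dbp, pp, map_))
    means: dict[tuple[str, str], float] = {}
    missing = []
    for p in PERIODS:
        vals = by_period[p]
        if not vals:
            missing.append(p)
        arr = np.array(vals) if vals else np.full((1, 4), np.nan)
        for k, trait in enumerate(("sbp", "dbp", "pp", "map")):
            means[(p, trait)] = float(arr[:, k].mean())
    return DerivedBP(record.pair_id, tuple(obs), means, tuple(missing))


def filter_eligible(records: list[PhenotypeRecord]) -> list[PhenotypeRecord]:
    """Exclude chronic hypertension and HDP, and deliveries before 34 weeks."""
    return [
        r
        for r in records
        if r.hypertension_flag == "none" and r.gestational_age_at_delivery >= 34
    ]


@dataclass(frozen=True)
class AdjustedWeight:
    pair_id: str
    bw_z: float
    pw_z: float


def chart_adjust(record: PhenotypeRecord, chart: ReferenceChart) -> AdjustedWeight:
    """Standardize birth and placental weight against the chart stratum for
    the completed (floored) gestational week, fetal sex and parity."""
    week = math.floor(record.gestational_age_at_delivery)
    bw_mean, bw_sd, pw_mean, pw_sd = chart.stratum(week, record.fetal_sex, record.parity)
    bw_z = (record.birth_weight - bw_mean) / bw_sd
    pw_z = (record.placental_weight - pw_mean) / pw_sd
    if not (np.isfinite(bw_z) and np.isfinite(pw_z)):
        raise ChartCoverageError(f"{record.pair_id}: non-finite adjusted weight")
    return AdjustedWeight(record.pair_id, bw_z, pw_z)


def zscale(values: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance transform (sample variance, n−1 denominator).

    Constant input is flagged with :class:`DegenerateInputWarning` and
    returned as all zeros instead of dividing by zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scaling needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("constant input to zscale; returning zeros", DegenerateInputWarning)
        return np.zeros_like(x)
    return (x - x.mean()) / sd
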