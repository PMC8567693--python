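"""Polygenic score construction by clumping and thresholding.

Variant QC (call rate, MAF, Hardy-Weinberg on founders, imputation DR2,
autosomes only), greedy LD clumping on cohort-internal maternal dosages,
p-value thresholding with dosage-weighted scoring and z-scaling, unweighted
SBP-oriented risk scores, subdivision by vasculature annotation, and
pleiotropy exclusion against auxiliary traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationRecord, PhasedTrioCohort, match_alleles

DEFAULT_THRESHOLDS = (1e-6, 1e-5, 1e-4, 1e-3)


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCThresholds:
    """Marker-level exclusion rules: call rate < 0.95, MAF < 0.01,
    Hardy-Weinberg p < 1e-5 (founders), imputation DR2 < 0.7 when present."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-5
    min_dr2: float = 0.7


@dataclass(frozen=True)
class ClumpParams:
    p1: float = 1.0
    p2: float = 1.0
    r2: float = 0.1
    kb: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.r2 < 1):
            raise ValueError("clump r2 must be in (0, 1)")
        if self.kb <= 0:
            raise ValueError("clump kb must be positive")


@dataclass
class PGSResult:
    threshold: float
    variant_ids: list[str]
    weights: pd.Series            # per variant, alt-dosage scale
    raw_score: pd.Series          # per mother
    z_score: pd.Series
    degenerate: bool = False
    adjusted_r2: float | None = None

    @property
    def empty(self) -> bool:
        return len(self.variant_ids) == 0


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg test on genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    nz = exp > 0
    chi2 = ((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum()
    return float(stats.chi2.sf(chi2, df=1))


def compute_qc(cohort: PhasedTrioCohort) -> pd.DataFrame:
    """Per-variant QC metrics: call rate over all samples; MAF and
    Hardy-Weinberg p over founders (parents); DR2 passed through."""
    h = cohort.haplotypes
    call_rate = (h >= 0).all(axis=2).mean(axis=0)

    fidx = [cohort.sample_index(s) for s in cohort.founders]
    fh = h[fidx].astype(float)
    fh[fh < 0] = np.nan
    dos = fh.sum(axis=2)  # founders x variants, NaN if missing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        af = np.nanmean(dos, axis=0) / 2.0
    af = np.nan_to_num(af, nan=0.0)
    maf = np.minimum(af, 1 - af)

    # vectorized 1-df chi-square HWE over founder genotype counts
    n_bb = np.nansum(dos == 0, axis=0).astype(float)   # hom ref
    n_ab = np.nansum(dos == 1, axis=0).astype(float)
    n_aa = np.nansum(dos == 2, axis=0).astype(float)   # hom alt
    n = n_aa + n_ab + n_bb
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = (2 * n_aa + n_ab) / (2 * n)
        exp = np.stack([n * p_hat ** 2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2])
        obs = np.stack([n_aa, n_ab, n_bb])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=0)
    hwe = stats.chi2.sf(chi2, df=1)
    hwe[n == 0] = 1.0

    return pd.DataFrame(
        {
            "variant_id": [v.id for v in cohort.variants],
            "chrom": [v.chrom for v in cohort.variants],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe,
            "dr2": cohort.dr2 if cohort.dr2 is not None else np.nan,
        }
    ).set_index("variant_id")


def qc_filter(
    cohort: PhasedTrioCohort,
    qc: pd.DataFrame | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[PhasedTrioCohort, pd.DataFrame]:
    """Drop failing variants; returns the filtered cohort and a per-criterion
    exclusion report."""
    qc = compute_qc(cohort) if qc is None else qc
    autosomes = {str(c) for c in range(1, 23)} | {f"chr{c}" for c in range(1, 23)}
    fails = pd.DataFrame(
        {
            "call_rate": qc["call_rate"] < thresholds.min_call_rate,
            "maf": qc["maf"] < thresholds.min_maf,
            "hwe": qc["hwe_p"] < thresholds.min_hwe_p,
            "dr2": qc["dr2"].notna() & (qc["dr2"] < thresholds.min_dr2),
            "non_autosomal": ~qc["chrom"].isin(autosomes),
        },
        index=qc.index,
    )
    keep = qc.index[~fails.any(axis=1)]
    if len(keep) == 0:
        raise QCError("no variants remain after QC")
    report = fails.copy()
    report["excluded"] = fails.any(axis=1)
    return cohort.subset_variants(keep), report


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; monomorphic
    columns get r2 = 0 against everything."""
    d = dosages - np.nanmean(dosages, axis=0)
    d = np.nan_to_num(d)
    sd = d.std(axis=0)
    sd[sd == 0] = np.inf
    c = (d.T @ d) / dosages.shape[0]
    r = c / np.outer(sd, sd)
    return r ** 2


def ld_clump(
    sumstats: pd.DataFrame,
    cohort: PhasedTrioCohort,
    params: ClumpParams = ClumpParams(),
) -> list[str]:
    """Greedy index-variant selection, PLINK style.

    Sort by ascending p (ties by chrom, pos); repeatedly take the best
    unclaimed variant as an index and claim every variant within +-kb whose
    r^2 with it (maternal dosages, cohort-internal) is >= params.r2.
    Returns index variant ids; no retained within-window pair has
    r^2 >= params.r2.
    """
    known = {v.id for v in cohort.variants}
    missing = set(sumstats["variant_id"]) - known
    if missing:
        raise KeyError(f"sumstat variants absent from cohort: {sorted(missing)[:5]}...")

    ss = sumstats[sumstats["p_value"] <= params.p1].copy()
    vmap = {v.id: v for v in cohort.variants}
    ss["chrom_key"] = [int(vmap[i].chrom.removeprefix("chr")) for i in ss["variant_id"]]
    ss["pos"] = [vmap[i].pos for i in ss["variant_id"]]
    ss = ss.sort_values(["p_value", "chrom_key", "pos"], kind="mergesort").reset_index(drop=True)

    dos = cohort.dosages(cohort.mothers)
    order = list(ss["variant_id"])
    cols = dos[order].to_numpy(dtype=float)
    r2 = _pairwise_r2(cols)
    chrom = ss["chrom_key"].to_numpy()
    pos = ss["pos"].to_numpy()
    pvals = ss["p_value"].to_numpy()
    window = params.kb * 1000.0

    claimed = np.zeros(len(order), dtype=bool)
    index_variants: list[str] = []
    for i in range(len(order)):
        if claimed[i]:
            continue
        index_variants.append(order[i])
        claimed[i] = True
        in_window = (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window) & ~claimed
        in_window &= pvals <= params.p2
        claimed |= in_window & (r2[i] >= params.r2)
    return index_variants


# ---------------------------------------------------------------------------
# thresholding and scoring
# ---------------------------------------------------------------------------


def threshold_and_score(
    sumstats: pd.DataFrame,
    cohort: PhasedTrioCohort,
    clumped_ids: list[str],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    trait_values: pd.Series | None = None,
) -> dict[float, PGSResult]:
    """Dosage-weighted PGS per p-value threshold over the clumped set.

    Per mother, raw score = sum over retained variants of (BP-increasing
    allele dosage x |normalized effect size|), i.e. effect alleles are
    oriented to the trait-increasing direction so weights are non-negative.
    Scores are z-scaled (zero mean, unit sample variance); a constant score
    is flagged degenerate rather than divided by zero.  When ``trait_values``
    is given, the adjusted R^2 of trait ~ score is recorded per threshold.
    """
    matched = match_alleles(sumstats, cohort).set_index("variant_id")
    matched = matched.loc[[v for v in clumped_ids if v in matched.index]]
    dos = cohort.dosages(cohort.mothers)

    out: dict[float, PGSResult] = {}
    for t in thresholds:
        sel = matched[matched["p_value"] <= t]
        ids = list(sel.index)
        if not ids:
            empty = pd.Series(dtype=float)
            out[t] = PGSResult(t, [], empty, pd.Series(0.0, index=dos.index),
                               pd.Series(0.0, index=dos.index), degenerate=True)
            continue
        beta_alt = sel["beta_alt"].astype(float)
        # orient each variant to its BP-increasing allele: dosage of the
        # increasing allele times |beta|; equals beta_alt-weighted alt dosage
        # up to a per-variant constant, so z-scores are identical.
        d = dos[ids].to_numpy(dtype=float)
        bv = beta_alt.to_numpy()
        inc_dos = np.where(bv >= 0, d, 2 - d)
        raw = pd.Series(inc_dos @ np.abs(bv), index=dos.index)
        sd = raw.std(ddof=1)
        degenerate = bool(sd == 0 or np.isnan(sd))
        z = (raw - raw.mean()) / sd if not degenerate else pd.Series(0.0, index=raw.index)
        adj_r2 = None
        if trait_values is not None and not degenerate:
            adj_r2 = _adjusted_r2(trait_values.reindex(raw.index), z)
        out[t] = PGSResult(t, ids, beta_alt, raw, z, degenerate, adj_r2)
    return out


def _adjusted_r2(y: pd.Series, x: pd.Series) -> float:
    import statsmodels.api as sm

    mask = y.notna() & x.notna()
    model = sm.OLS(y[mask].to_numpy(), sm.add_constant(x[mask].to_numpy())).fit()
    return float(model.rsquared_adj)


def select_threshold(results: dict[float, PGSResult]) -> float:
    """The threshold whose score maximizes adjusted R^2 against the trait."""
    scored = {t: r.adjusted_r2 for t, r in results.items() if r.adjusted_r2 is not None}
    if not scored:
        raise ValueError("no threshold has an adjusted R^2 (no trait supplied or all empty)")
    return max(scored, key=scored.__getitem__)


# ---------------------------------------------------------------------------
# SBP-oriented unweighted scores
# ---------------------------------------------------------------------------


def orient_sbp_increasing(
    annotation: dict[str, AnnotationRecord], variant_ids: list[str]
) -> dict[str, str]:
    """Counted allele per variant: always the SBP-increasing allele, also for
    the DBP-discordant variants (SBP, MAP and PP agree in direction there)."""
    missing = [v for v in variant_ids if v not in annotation]
    if missing:
        raise KeyError(f"variants missing from annotation: {missing}")
    return {v: annotation[v].sbp_increasing_allele for v in variant_ids}


def counted_allele_dosage(
    cohort: PhasedTrioCohort, counted_alleles: dict[str, str], samples: list[str] | None = None
) -> pd.DataFrame:
    """Dosage of the counted (SBP-increasing) allele per sample x variant."""
    samples = cohort.mothers if samples is None else samples
    dos = cohort.dosages(samples)
    vmap = {v.id: v for v in cohort.variants}
    out = {}
    for vid, allele in counted_alleles.items():
        v = vmap[vid]
        if allele == v.alt:
            out[vid] = dos[vid]
        elif allele == v.ref:
            out[vid] = 2 - dos[vid]
        else:
            raise ValueError(f"{vid}: counted allele {allele} matches neither {v.ref} nor {v.alt}")
    return pd.DataFrame(out)


def unweighted_score(
    cohort: PhasedTrioCohort,
    counted_alleles: dict[str, str],
    subset: list[str],
    samples: list[str] | None = None,
) -> pd.Series:
    """Unweighted count of SBP-increasing alleles over ``subset``; integer in
    [0, 2 * |subset|] per sample."""
    if not subset:
        raise ValueError("unweighted score requires a non-empty variant subset")
    sub = {v: counted_alleles[v] for v in subset}
    return counted_allele_dosage(cohort, sub, samples).sum(axis=1).astype(int)


def subdivide_by_class(
    annotation: dict[str, AnnotationRecord], variant_ids: list[str]
) -> dict[str, list[str]]:
    """Disjoint, exhaustive partition into vasculature-related / unlikely
    related / unknown."""
    unlabeled = [v for v in variant_ids if v not in annotation]
    if unlabeled:
        raise KeyError(f"unlabeled variants: {unlabeled}")
    out: dict[str, list[str]] = {"vasculature-related": [], "unlikely related": [], "unknown": []}
    for v in variant_ids:
        out[annotation[v].vasc_class].append(v)
    return out


def exclude_pleiotropic(
    variant_ids: list[str],
    aux_sumstats: dict[str, pd.DataFrame],
    threshold: float,
) -> list[str]:
    """Remove variants associated with any auxiliary trait (BMI/T2D/HbA1c) at
    p <= threshold; variants absent from an auxiliary table are kept."""
    flagged: set[str] = set()
    for df in aux_sumstats.values():
        hit = df.loc[df["p_value"] <= threshold, "variant_id"]
        flagged.update(hit)
    return [v for v in variant_ids if v not in flagged]
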