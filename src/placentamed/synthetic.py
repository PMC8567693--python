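"""Synthetic trio-cohort generator with retained ground truth.

Emulates the study substrate end to end: LD-blocked phased haplotypes,
Mendelian mother–father–child transmission, GWAS summary statistics for the
blood-pressure traits (plus BMI/T2D/HbA1c auxiliaries for pleiotropy
screening), a linear mediation structure

    PGS(z)  --a-->  placental weight(z)  --b-->  birth weight(z)

with a log-BMI confounder acting on both mediator and outcome and a small
direct path c', and sigmoidal estimated-fetal-weight (EFW) trajectories whose
third-trimester weekly velocity is shifted by the mediator.  All generating
quantities (causal betas, transmitted-haplotype identities, path
coefficients, true growth curves) are recorded in :class:`SimulationTruth`
so every downstream stage can be tested against known truth.

Design notes
------------
* No recombination within the simulated region: each child haplotype is an
  exact copy of one parental haplotype, keeping transmission truth exact.
* Within an LD block all variants share one MAF and adjacent variants are
  coupled by a copying Markov chain with copy probability sqrt(r2), so the
  adjacent-variant allele correlation is sqrt(r2) and r-squared is r2.
* Causal variants sit one-per-block on block index positions, so LD clumping
  at r2 < 1 retains them all and the thresholded score recovers the liability.
* Grams-scale weights are back-transformed through the packaged reference
  chart, making chart adjustment an exact inverse in the noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io_formats import (
    PhasedTrioCohort,
    PhenotypeRecord,
    ReferenceChart,
    Variant,
    load_default_chart,
    write_phased_vcf,
    write_phenotypes,
    write_summary_stats,
    write_ultrasound,
)

DEFAULT_H2 = {"SBP": 0.0569, "DBP": 0.04, "MAP": 0.0496, "PP": 0.0438}

# cross-trait scaling of emitted effect sizes relative to the SBP betas;
# BP traits are strongly genetically correlated, auxiliaries are null unless
# pleiotropic variants are planted.
TRAIT_SCALE = {"SBP": 1.0, "MAP": 0.9, "DBP": 0.75, "PP": 0.55}
AUX_TRAITS = ("BMI", "T2D", "HbA1c")


class ConfigError(ValueError):
    """Simulation configuration is infeasible or incomplete."""


@dataclass
class SimulationConfig:
    """Generating conditions for the synthetic cohort.

    The defaults are the study conditions: 93 mother-child pairs, path
    coefficients equal to the published point estimates (exposure->mediator
    a = -0.396, mediator->outcome b = 0.661, direct c' = -0.049), SNP
    heritabilities 0.0569/0.04/0.0496/0.0438 for SBP/DBP/MAP/PP, and a
    GWAS base sample of 136 000.
    """

    seed: int
    n_trios: int = 93
    n_blocks: int = 600
    block_size: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    within_block_r2: float = 0.8
    pool_size: int | None = None          # default 4 * n_trios
    n_causal: int = 60
    # mediation structure (z scales)
    a: float = -0.396
    b: float = 0.661
    c_direct: float = -0.049
    g_bmi_m: float = 0.15
    g_bmi_y: float = 0.10
    h2: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_H2))
    # observed-BP generation; the published cohort showed no PGS <-> measured
    # BP association at n = 93, so the liability share defaults small.
    bp_pgs_share: float = 0.02
    bp_visit_sd: float = 6.0
    # summary-statistics emission
    gwas_n: int = 136_000
    n_pleiotropic: int = 0
    # ultrasound / growth
    velocity_link: float = 30.0           # g/week per SD of mediator, weeks > 30
    efw_noise: float = 0.05               # multiplicative log-SD
    n_obs_range: tuple[int, int] = (6, 12)
    # hypertension flags (excluded downstream; default absent as in the cohort)
    frac_hdp: float = 0.0
    frac_chronic: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 + 1e-12):
            raise ConfigError(f"MAF bounds must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0 <= self.within_block_r2 < 1):
            raise ConfigError("within_block_r2 must be in [0, 1)")
        for name in ("a", "b", "c_direct"):
            if abs(getattr(self, name)) >= 1:
                raise ConfigError(f"|{name}| must be < 1")
        if self.n_trios < 1:
            raise ConfigError("n_trios must be >= 1")
        if self.n_obs_range[0] < 4:
            raise ConfigError("at least 4 ultrasound observations are required for a spline fit")
        if self.n_causal > self.n_blocks:
            raise ConfigError("n_causal cannot exceed n_blocks (one causal variant per block)")


@dataclass
class HaplotypePool:
    """Phased haplotypes in LD blocks; rows are haplotypes, columns variants."""

    haplotypes: np.ndarray          # (pool_size, n_variants) int8
    variants: list[Variant]
    block_id: np.ndarray            # (n_variants,)
    maf: np.ndarray                 # per-variant generating MAF

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analyst would not."""

    pair_ids: list[str]
    causal_mask: np.ndarray          # per variant
    gen_beta_alt: np.ndarray         # per-alt-copy effect, trait SD units
    maternal_transmitted: np.ndarray  # index in {0,1} of transmitted maternal hap
    paternal_transmitted: np.ndarray
    a: float = np.nan
    b: float = np.nan
    c_direct: float = np.nan
    pgs_z: np.ndarray | None = None
    mediator_z: np.ndarray | None = None
    outcome_z: np.ndarray | None = None
    logbmi_z: np.ndarray | None = None
    true_efw: pd.DataFrame | None = None       # weeks x pairs, grams
    true_velocity: pd.DataFrame | None = None  # weeks x pairs, g/week

    @property
    def true_acme(self) -> float:
        return self.a * self.b

    @property
    def true_total(self) -> float:
        return self.a * self.b + self.c_direct


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------


def simulate_haplotype_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> HaplotypePool:
    """Markov-coupled LD blocks: adjacent within-block r^2 targets
    ``config.within_block_r2``; blocks are mutually independent and spaced
    2 Mb apart (outside the 1 Mb clumping window)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_pool = config.pool_size or 4 * config.n_trios
    q = float(np.sqrt(config.within_block_r2))

    blocks_per_chrom = int(np.ceil(config.n_blocks / 22))
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    block_id = np.repeat(np.arange(config.n_blocks), config.block_size)
    mafs = np.empty(config.n_blocks * config.block_size)
    allele_pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]

    for b in range(config.n_blocks):
        p = rng.uniform(*config.maf_range)
        chrom = str(b // blocks_per_chrom + 1)
        base_pos = (b % blocks_per_chrom) * 2_000_000 + 1_000_000
        hap = rng.random(n_pool) < p
        for j in range(config.block_size):
            if j > 0:
                fresh = rng.random(n_pool) < p
                copy = rng.random(n_pool) < q
                hap = np.where(copy, hap, fresh)
            k = b * config.block_size + j
            ref, alt = allele_pairs[k % len(allele_pairs)]
            variants.append(Variant(id=f"rsv{k:05d}", chrom=chrom, pos=base_pos + j * 1000, ref=ref, alt=alt))
            cols.append(hap.astype(np.int8).copy())
            mafs[k] = p
    return HaplotypePool(
        haplotypes=np.stack(cols, axis=1),
        variants=variants,
        block_id=block_id,
        maf=mafs,
    )


def sample_dosages(pool: HaplotypePool, n: int, rng: np.random.Generator) -> np.ndarray:
    """Alt-allele dosages for ``n`` individuals drawn as random haplotype pairs."""
    i1 = rng.integers(0, pool.haplotypes.shape[0], n)
    i2 = rng.integers(0, pool.haplotypes.shape[0], n)
    return pool.haplotypes[i1].astype(np.int16) + pool.haplotypes[i2]


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------


def simulate_trios(
    pool: HaplotypePool, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PhasedTrioCohort, SimulationTruth]:
    """Assign two pool haplotypes to each parent; each child receives one
    maternal and one paternal haplotype chosen uniformly, with no
    recombination.  Child haplotype order is (maternal, paternal); the
    transmitted indices are recorded in the truth object."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_trios
    n_pool = pool.haplotypes.shape[0]

    samples: list[str] = []
    roles: dict[str, str] = {}
    pedigree: dict[str, tuple[str, str | None]] = {}
    hap_rows: list[np.ndarray] = []

    m_trans = rng.integers(0, 2, n)
    p_trans = rng.integers(0, 2, n)
    pair_ids = [f"P{i + 1:04d}" for i in range(n)]
    for i in range(n):
        mother, father, child = f"M{i + 1:04d}", f"F{i + 1:04d}", f"C{i + 1:04d}"
        mh = pool.haplotypes[rng.integers(0, n_pool, 2)]
        fh = pool.haplotypes[rng.integers(0, n_pool, 2)]
        ch = np.stack([mh[m_trans[i]], fh[p_trans[i]]])
        for s, role, h in ((mother, "mother", mh), (father, "father", fh), (child, "child", ch)):
            samples.append(s)
            roles[s] = role
            hap_rows.append(h.T)  # (n_variants, 2)
        pedigree[child] = (mother, father)

    cohort = PhasedTrioCohort(
        variants=list(pool.variants),
        samples=samples,
        roles=roles,
        pedigree=pedigree,
        haplotypes=np.stack(hap_rows, axis=0).astype(np.int8),
        dr2=np.ones(pool.n_variants),
    )
    truth = SimulationTruth(
        pair_ids=pair_ids,
        causal_mask=np.zeros(pool.n_variants, dtype=bool),
        gen_beta_alt=np.zeros(pool.n_variants),
        maternal_transmitted=m_trans,
        paternal_transmitted=p_trans,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# phenotypes + summary statistics
# ---------------------------------------------------------------------------


def _zscale(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigError("degenerate (constant) generated variable")
    return (x - x.mean()) / sd


def simulate_phenotypes(
    cohort: PhasedTrioCohort,
    truth: SimulationTruth,
    pool: HaplotypePool,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    chart: ReferenceChart | None = None,
) -> tuple[list[PhenotypeRecord], dict[str, pd.DataFrame]]:
    """Generate phenotypes with the configured mediation structure, and the
    GWAS summary-statistics tables the PGS stage will consume.

    Mediator and outcome are built on z scales with unit population variance:
    residual SDs absorb what the systematic paths do not explain; a negative
    residual variance raises :class:`ConfigError`.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    chart = chart or load_default_chart()
    n = config.n_trios

    # --- causal architecture: one index variant per causal block -----------
    causal_blocks = rng.choice(config.n_blocks, size=config.n_causal, replace=False)
    causal_idx = causal_blocks * config.block_size
    truth.causal_mask[:] = False
    truth.causal_mask[causal_idx] = True
    h2_sbp = config.h2.get("SBP", DEFAULT_H2["SBP"])
    p = pool.maf[causal_idx]
    mag = np.sqrt(h2_sbp / (config.n_causal * 2 * p * (1 - p)))
    signs = rng.choice([-1.0, 1.0], size=config.n_causal)
    truth.gen_beta_alt[:] = 0.0
    truth.gen_beta_alt[causal_idx] = signs * mag

    # --- maternal genetic liability and mediation structure ----------------
    mothers = cohort.mothers
    mhap = cohort.haplotypes[[cohort.sample_index(s) for s in mothers]]
    mdos = mhap.sum(axis=2).astype(float)          # (n, n_variants)
    liability = mdos @ truth.gen_beta_alt
    pgs_z = _zscale(liability)

    bmi = np.exp(rng.normal(np.log(21.0), 0.12, n))
    logbmi_z = _zscale(np.log(bmi))

    var_em = 1 - config.a ** 2 - config.g_bmi_m ** 2
    if var_em <= 0:
        raise ConfigError("mediator residual variance is non-positive; reduce a or g_bmi_m")
    mediator_z = config.a * pgs_z + config.g_bmi_m * logbmi_z + np.sqrt(var_em) * rng.standard_normal(n)

    var_sys = (
        config.b ** 2 + config.c_direct ** 2 + config.g_bmi_y ** 2
        + 2 * config.b * config.c_direct * config.a
        + 2 * config.b * config.g_bmi_y * config.g_bmi_m
    )
    var_ey = 1 - var_sys
    if var_ey <= 0:
        raise ConfigError("outcome residual variance is non-positive; reduce b/c_direct/g_bmi_y")
    outcome_z = (
        config.b * mediator_z + config.c_direct * pgs_z + config.g_bmi_y * logbmi_z
        + np.sqrt(var_ey) * rng.standard_normal(n)
    )

    truth.a, truth.b, truth.c_direct = config.a, config.b, config.c_direct
    truth.pgs_z, truth.mediator_z, truth.outcome_z = pgs_z, mediator_z, outcome_z
    truth.logbmi_z = logbmi_z

    # --- grams-scale weights through the chart -----------------------------
    ga = np.round(np.clip(40.0 + rng.normal(0, 1.2, n), 37.0, 42.4), 1)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    parity = np.where(rng.random(n) < 0.4, "parous", "nulliparous")
    flags = np.array(["none"] * n, dtype=object)
    u = rng.random(n)
    flags[u < config.frac_hdp] = "HDP"
    flags[(u >= config.frac_hdp) & (u < config.frac_hdp + config.frac_chronic)] = "chronic"

    # --- observed blood pressure around a liability with a small PGS share --
    s = config.bp_pgs_share
    bp_liab = np.sqrt(s) * pgs_z + np.sqrt(1 - s) * rng.standard_normal(n)
    dbp0 = 65 + 6 * (0.6 * bp_liab + 0.8 * rng.standard_normal(n))
    pp0 = np.maximum(20.0, 42 + 5 * rng.standard_normal(n))
    visit_weeks = (10, 14, 18, 22, 26, 30, 34, 36, 38)

    records: list[PhenotypeRecord] = []
    for i, pid in enumerate(truth.pair_ids):
        week = int(np.floor(ga[i]))
        bw_mean, bw_sd, pw_mean, pw_sd = chart.stratum(week, sex[i], parity[i])
        obs = []
        for w in visit_weeks:
            trend = -5 * np.exp(-(((w - 22) / 8.0) ** 2)) + 0.25 * max(0, w - 30)
            dbp_w = dbp0[i] + 0.6 * trend + rng.normal(0, config.bp_visit_sd * 0.7)
            pp_w = max(15.0, pp0[i] + 0.4 * trend + rng.normal(0, config.bp_visit_sd * 0.6))
            obs.append((float(w), round(dbp_w + pp_w, 2), round(dbp_w, 2)))
        records.append(
            PhenotypeRecord(
                pair_id=pid,
                pre_pregnancy_bmi=round(float(bmi[i]), 3),
                bp_obs=tuple(obs),
                birth_weight=float(bw_mean + outcome_z[i] * bw_sd),
                placental_weight=float(pw_mean + mediator_z[i] * pw_sd),
                gestational_age_at_delivery=float(ga[i]),
                fetal_sex=str(sex[i]),
                parity=str(parity[i]),
                hypertension_flag=str(flags[i]),
            )
        )

    sumstats = _emit_summary_stats(pool, truth, config, rng)
    return records, sumstats


def _emit_summary_stats(
    pool: HaplotypePool, truth: SimulationTruth, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Per-trait tables: emitted beta = generating beta + sampling noise at
    the GWAS base sample size; null variants carry N(0,1) z-scores so
    p-value thresholding behaves realistically."""
    p = pool.maf
    se = 1.0 / np.sqrt(2 * p * (1 - p) * config.gwas_n)
    base = {
        "variant_id": [v.id for v in pool.variants],
        "chrom": [v.chrom for v in pool.variants],
        "pos": [v.pos for v in pool.variants],
        "effect_allele": [v.alt for v in pool.variants],
        "other_allele": [v.ref for v in pool.variants],
    }
    out: dict[str, pd.DataFrame] = {}
    from scipy.stats import norm

    for trait in ("SBP", "DBP", "MAP", "PP"):
        scale = TRAIT_SCALE[trait]
        z = scale * truth.gen_beta_alt / se + rng.standard_normal(pool.n_variants)
        out[trait] = pd.DataFrame(
            {**base, "beta": z * se, "p_value": np.maximum(2 * norm.sf(np.abs(z)), 1e-300), "trait": trait}
        )
    pleio = (
        rng.choice(np.flatnonzero(truth.causal_mask), size=config.n_pleiotropic, replace=False)
        if config.n_pleiotropic
        else np.array([], dtype=int)
    )
    for trait in AUX_TRAITS:
        z = rng.standard_normal(pool.n_variants)
        z[pleio] = 8.0 * rng.choice([-1.0, 1.0], size=pleio.size)
        out[trait] = pd.DataFrame(
            {**base, "beta": z * se, "p_value": np.maximum(2 * norm.sf(np.abs(z)), 1e-300), "trait": trait}
        )
    return out


def simulate_trait(liability: np.ndarray, h2: float, rng: np.random.Generator) -> np.ndarray:
    """A quantitative trait whose PGS-explained variance is ``h2``.

    ``liability`` is the genetic score (variance ~ h2 by construction of the
    generating betas); environmental noise supplies the remaining 1 - h2.
    """
    return liability - liability.mean() + rng.standard_normal(liability.size) * np.sqrt(1 - h2)


# ---------------------------------------------------------------------------
# ultrasound
# ---------------------------------------------------------------------------

TRUE_WEEK_GRID = np.arange(10, 41)


def simulate_ultrasound(
    truth: SimulationTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, list[tuple[float, float]]]:
    """Sigmoidal EFW trajectories; after week 30 the weekly increment is
    shifted by ``velocity_link * mediator_z`` (g/week), so a smaller placenta
    slows late-gestation growth.  6-12 observations per fetus between weeks
    12 and 38 with multiplicative log-normal noise."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if truth.mediator_z is None:
        raise ConfigError("phenotypes must be simulated before ultrasound")
    n = len(truth.pair_ids)

    K = 4600 * np.exp(0.06 * rng.standard_normal(n))
    t0 = 31 + rng.normal(0, 0.8, n)
    k = 0.17 * np.exp(rng.normal(0, 0.05, n))
    weeks = TRUE_WEEK_GRID.astype(float)

    base = K[:, None] / (1 + np.exp(-k[:, None] * (weeks[None, :] - t0[:, None])))
    shift = config.velocity_link * truth.mediator_z[:, None] * np.maximum(0, weeks[None, :] - 30)
    efw = np.maximum(base + shift, 50.0)

    true_efw = pd.DataFrame(efw.T, index=TRUE_WEEK_GRID, columns=truth.pair_ids)
    truth.true_efw = true_efw
    truth.true_velocity = true_efw.diff().iloc[1:]

    lo, hi = config.n_obs_range
    out: dict[str, list[tuple[float, float]]] = {}
    for i, pid in enumerate(truth.pair_ids):
        # checkups run to term (weekly beyond week 36), so the last scan sits
        # at 36-38 weeks and the weekly grid covers the late-gestation window
        n_obs = int(rng.integers(lo, hi + 1))
        first = int(rng.integers(12, 17))
        last = int(rng.integers(36, 39))
        middle = rng.choice(np.arange(first + 1, last), size=n_obs - 2, replace=False)
        obs_weeks = np.sort(np.concatenate([[first], middle, [last]])).astype(float)
        obs_weeks += rng.uniform(-0.35, 0.35, n_obs)
        curve = PchipInterpolator(weeks, efw[i])
        vals = curve(obs_weeks)
        if config.efw_noise > 0:
            vals = vals * np.exp(rng.normal(0, config.efw_noise, n_obs))
        out[pid] = [(float(w), float(v)) for w, v in zip(obs_weeks, vals)]
    return out


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    pool: HaplotypePool
    cohort: PhasedTrioCohort
    truth: SimulationTruth
    phenotypes: list[PhenotypeRecord]
    sumstats: dict[str, pd.DataFrame]
    ultrasound: dict[str, list[tuple[float, float]]]
    chart: ReferenceChart


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run all generator stages under one seed fan-out."""
    ss = np.random.SeedSequence(config.seed)
    r_pool, r_trio, r_pheno, r_us = (np.random.default_rng(s) for s in ss.spawn(4))
    chart = load_default_chart()
    pool = simulate_haplotype_pool(config, r_pool)
    cohort, truth = simulate_trios(pool, config, r_trio)
    phenos, sumstats = simulate_phenotypes(cohort, truth, pool, config, r_pheno, chart)
    ultrasound = simulate_ultrasound(truth, config, r_us)
    return SyntheticCohort(config, pool, cohort, truth, phenos, sumstats, ultrasound, chart)


def write_cohort(bundle: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write VCF + pedigree + all TSVs + a truth table; byte-identical for
    identical seed and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "pedigree.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "bp": outdir / "bp_observations.tsv",
        "ultrasound": outdir / "ultrasound.tsv",
        "chart": outdir / "reference_chart.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_phased_vcf(bundle.cohort, paths["vcf"], paths["ped"])
    write_phenotypes(bundle.phenotypes, paths["phenotypes"], paths["bp"])
    write_ultrasound(bundle.ultrasound, paths["ultrasound"])
    bundle.chart.table.to_csv(paths["chart"], sep="\t", index=False, float_format="%.10g")
    for trait, df in bundle.sumstats.items():
        p = outdir / f"sumstats_{trait}.tsv"
        write_summary_stats(df, p)
        paths[f"sumstats_{trait}"] = p
    t = bundle.truth
    pd.DataFrame(
        {
            "pair_id": t.pair_ids,
            "pgs_z": t.pgs_z,
            "mediator_z": t.mediator_z,
            "outcome_z": t.outcome_z,
            "logbmi_z": t.logbmi_z,
            "maternal_transmitted": t.maternal_transmitted,
            "paternal_transmitted": t.paternal_transmitted,
        }
    ).to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
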