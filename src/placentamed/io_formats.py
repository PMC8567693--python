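"""Readers and writers for the external formats consumed by the pipeline.

Phased trio genotypes travel as a standard VCF (GT fields ``|``-separated)
with a pedigree sidecar TSV (columns ``child``, ``mother``, ``father``;
``father`` may be ``NA`` for mother–child duos).  GWAS summary statistics,
phenotypes, blood-pressure observations, ultrasound series, the perinatal
reference chart and the variant annotation table are tab-delimited with
documented headers.  Every reader validates on entry and every reader/writer
pair round-trips losslessly on valid input.

Coordinates are 1-based throughout, as in VCF.  Only biallelic autosomal
SNPs are accepted; genotypes must be phased.  Missing alleles (``.``) are
stored as -1 and flagged for call-rate QC downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("placentamed")

NUCLEOTIDES = frozenset("ACGT")
TRAITS = ("SBP", "DBP", "MAP", "PP", "BMI", "T2D", "HbA1c")
VASC_CLASSES = ("vasculature-related", "unlikely related", "unknown")
PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ValidationError(ValueError):
    """Input violates a documented format contract."""


class PedigreeError(ValidationError):
    """Pedigree sidecar is inconsistent with the VCF samples."""


class PhasingError(ValidationError):
    """Genotypes are not phased ('/'-separated GT)."""


class ChartCoverageError(KeyError):
    """Reference chart lacks a stratum observed in the cohort."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A biallelic autosomal SNP, 1-based position."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.id}: ref == alt ({self.ref})")
        for a in (self.ref, self.alt):
            if a not in NUCLEOTIDES:
                raise ValidationError(f"{self.id}: allele {a!r} is not a single nucleotide")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position {self.pos} < 1")

    @property
    def is_palindromic(self) -> bool:
        return (self.ref, self.alt) in PALINDROMIC


@dataclass
class PhasedTrioCohort:
    """Phased haplotypes for mother/father/child samples with pedigree links.

    ``haplotypes`` has shape (n_samples, n_variants, 2) with entries in
    {0, 1, -1}; -1 marks a missing allele.  Index 0 of the last axis is the
    first written haplotype; for simulated children it is the maternal one,
    but no analysis code relies on that convention.
    """

    variants: list[Variant]
    samples: list[str]
    roles: dict[str, str]                      # sample -> mother|father|child
    pedigree: dict[str, tuple[str, str | None]]  # child -> (mother, father|None)
    haplotypes: np.ndarray
    dr2: np.ndarray | None = None              # per-variant imputation quality

    def __post_init__(self) -> None:
        n_s, n_v = len(self.samples), len(self.variants)
        if self.haplotypes.shape != (n_s, n_v, 2):
            raise ValidationError(
                f"haplotype matrix shape {self.haplotypes.shape} != {(n_s, n_v, 2)}"
            )
        h = self.haplotypes
        if ((h < -1) | (h > 1)).any():
            raise ValidationError("haplotype alleles must be in {0,1} (-1 = missing)")
        for child, (mother, father) in self.pedigree.items():
            if mother not in self.roles:
                raise PedigreeError(f"child {child}: mother {mother} not in cohort")
            if father is not None and father not in self.roles:
                raise PedigreeError(f"child {child}: father {father} not in cohort")
        _check_sorted(self.variants)
        self._index = {s: i for i, s in enumerate(self.samples)}
        self._vindex = {v.id: i for i, v in enumerate(self.variants)}

    # -- accessors ---------------------------------------------------------
    def sample_index(self, sample: str) -> int:
        return self._index[sample]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id} absent from cohort") from None

    @property
    def mothers(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "mother"]

    @property
    def fathers(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "father"]

    @property
    def children(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "child"]

    @property
    def founders(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] != "child"]

    def dosages(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        """Alt-allele dosage (0/1/2) per sample x variant; NaN if any allele missing."""
        idx = [self.sample_index(s) for s in (samples if samples is not None else self.samples)]
        h = self.haplotypes[idx].astype(float)
        h[h < 0] = np.nan
        d = h.sum(axis=2)
        return pd.DataFrame(
            d,
            index=list(samples if samples is not None else self.samples),
            columns=[v.id for v in self.variants],
        )

    def subset_variants(self, keep_ids: Iterable[str]) -> "PhasedTrioCohort":
        keep = set(keep_ids)
        mask = [i for i, v in enumerate(self.variants) if v.id in keep]
        return PhasedTrioCohort(
            variants=[self.variants[i] for i in mask],
            samples=list(self.samples),
            roles=dict(self.roles),
            pedigree=dict(self.pedigree),
            haplotypes=self.haplotypes[:, mask, :].copy(),
            dr2=None if self.dr2 is None else self.dr2[mask].copy(),
        )


def _check_sorted(variants: Sequence[Variant]) -> None:
    keys = [(_chrom_sort_key(v.chrom), v.pos) for v in variants]
    if any(b <= a for a, b in zip(keys, keys[1:])):
        raise ValidationError("variants are not strictly increasing by (chrom, pos)")


def _chrom_sort_key(chrom: str) -> int:
    c = chrom.removeprefix("chr")
    if not c.isdigit():
        raise ValidationError(f"non-autosomal chromosome {chrom!r} not supported")
    return int(c)


@dataclass(frozen=True)
class PhenotypeRecord:
    pair_id: str
    pre_pregnancy_bmi: float           # kg/m^2
    bp_obs: tuple                      # ((week, sbp, dbp), ...)
    birth_weight: float                # g
    placental_weight: float            # g
    gestational_age_at_delivery: float  # decimal weeks
    fetal_sex: str                     # female|male
    parity: str                        # nulliparous|parous
    hypertension_flag: str = "none"    # none|chronic|HDP

    def __post_init__(self) -> None:
        if self.pre_pregnancy_bmi <= 0:
            raise ValidationError(f"{self.pair_id}: BMI must be positive")
        for week, sbp, dbp in self.bp_obs:
            if not (sbp > dbp > 0):
                raise ValidationError(
                    f"{self.pair_id}: BP observation at week {week} violates sbp > dbp > 0"
                )
        if self.hypertension_flag not in ("none", "chronic", "HDP"):
            raise ValidationError(f"{self.pair_id}: bad hypertension flag {self.hypertension_flag}")
        if self.fetal_sex not in ("female", "male"):
            raise ValidationError(f"{self.pair_id}: bad fetal_sex {self.fetal_sex}")
        if self.parity not in ("nulliparous", "parous"):
            raise ValidationError(f"{self.pair_id}: bad parity {self.parity}")


class ReferenceChart:
    """Birth- and placental-weight means/SDs by (gestational week, sex, parity)."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"week", "fetal_sex", "parity", "bw_mean", "bw_sd", "pw_mean", "pw_sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"chart missing columns: {sorted(missing)}")
        if (table[["bw_sd", "pw_sd"]] <= 0).any().any():
            raise ValidationError("chart SDs must all be positive")
        self.table = table.reset_index(drop=True)
        self._lookup = {
            (int(r.week), r.fetal_sex, r.parity): (r.bw_mean, r.bw_sd, r.pw_mean, r.pw_sd)
            for r in table.itertuples()
        }

    def stratum(self, week: int, fetal_sex: str, parity: str) -> tuple[float, float, float, float]:
        key = (int(week), fetal_sex, parity)
        if key not in self._lookup:
            raise ChartCoverageError(f"reference chart lacks stratum {key}")
        return self._lookup[key]


@dataclass(frozen=True)
class AnnotationRecord:
    variant_id: str
    vasc_class: str
    sbp_increasing_allele: str
    trait_memberships: frozenset
    dbp_discordant: bool

    def __post_init__(self) -> None:
        if self.vasc_class not in VASC_CLASSES:
            raise ValidationError(
                f"{self.variant_id}: vasc_class {self.vasc_class!r} not in {VASC_CLASSES}"
            )
        if self.sbp_increasing_allele not in NUCLEOTIDES:
            raise ValidationError(f"{self.variant_id}: bad SBP-increasing allele")
        bad = self.trait_memberships - {"SBP", "DBP", "MAP", "PP"}
        if bad:
            raise ValidationError(f"{self.variant_id}: unknown trait memberships {sorted(bad)}")


# ---------------------------------------------------------------------------
# phased VCF + pedigree
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> dict[str, tuple[str, str | None]]:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    required = {"child", "mother", "father"}
    if missing := required - set(ped.columns):
        raise PedigreeError(f"pedigree missing columns {sorted(missing)}")
    out: dict[str, tuple[str, str | None]] = {}
    for row in ped.itertuples():
        if pd.isna(row.mother) or row.mother in ("", "NA"):
            raise PedigreeError(f"child {row.child} has no mother")
        father = None if (pd.isna(row.father) or row.father in ("", "NA")) else row.father
        out[row.child] = (row.mother, father)
    return out


def read_phased_vcf(vcf_path: str | Path, ped_path: str | Path) -> PhasedTrioCohort:
    """Parse a phased biallelic-SNP VCF plus pedigree sidecar into a cohort.

    Multi-allelic or non-SNP records and unphased ('/') genotypes raise;
    missing alleles ('.') are kept as -1 and left to call-rate QC.
    """
    pedigree = read_pedigree(ped_path)
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    roles = _roles_from_pedigree(pedigree, samples)
    header_has_dr2 = "DR2" in vf.header.info

    variants: list[Variant] = []
    haps: list[np.ndarray] = []
    dr2: list[float] = []
    has_dr2 = False
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValidationError(f"{rec.id or rec.pos}: multi-allelic records are rejected")
        variants.append(
            Variant(
                id=rec.id or f"{rec.chrom}:{rec.pos}",
                chrom=str(rec.chrom),
                pos=rec.pos,
                ref=str(rec.ref).upper(),
                alt=str(rec.alts[0]).upper(),
            )
        )
        col = np.empty((len(samples), 2), dtype=np.int8)
        for j, s in enumerate(samples):
            call = rec.samples[s]
            alleles = call["GT"]
            if alleles is None or len(alleles) != 2:
                raise ValidationError(f"{rec.id}: sample {s} has a non-diploid GT")
            if not call.phased and None not in alleles and alleles[0] != alleles[1]:
                raise PhasingError(f"{rec.id}: sample {s} genotype is unphased")
            if not call.phased and None in alleles:
                pass  # missing genotype, phase flag meaningless
            elif not call.phased:
                # homozygous unphased e.g. "0/0": pysam reports phased=False;
                # phase is irrelevant for homozygotes, accept.
                pass
            col[j] = [(-1 if a is None else int(a)) for a in alleles]
        haps.append(col)
        v_dr2 = rec.info.get("DR2", None) if header_has_dr2 else None
        if v_dr2 is not None:
            has_dr2 = True
            v_dr2 = float(v_dr2[0] if isinstance(v_dr2, tuple) else v_dr2)
        dr2.append(np.nan if v_dr2 is None else v_dr2)
    vf.close()
    if not variants:
        raise ValidationError(f"{vcf_path}: no variant records")

    return PhasedTrioCohort(
        variants=variants,
        samples=samples,
        roles=roles,
        pedigree=pedigree,
        haplotypes=np.stack(haps, axis=1),
        dr2=np.asarray(dr2) if has_dr2 else None,
    )


def _roles_from_pedigree(
    pedigree: Mapping[str, tuple[str, str | None]], samples: Sequence[str]
) -> dict[str, str]:
    roles: dict[str, str] = {}
    present = set(samples)
    for child, (mother, father) in pedigree.items():
        if child not in present:
            raise PedigreeError(f"pedigree child {child} absent from VCF")
        if mother not in present:
            raise PedigreeError(f"mother {mother} of {child} absent from VCF")
        roles[child] = "child"
        roles[mother] = "mother"
        if father is not None:
            if father not in present:
                raise PedigreeError(f"father {father} of {child} absent from VCF")
            roles[father] = "father"
    unassigned = present - set(roles)
    if unassigned:
        raise PedigreeError(f"samples without pedigree role: {sorted(unassigned)}")
    return roles


def write_phased_vcf(cohort: PhasedTrioCohort, vcf_path: str | Path, ped_path: str | Path | None = None) -> None:
    """Write an uncompressed phased VCF (and optional pedigree sidecar)."""
    lines = ["##fileformat=VCFv4.2"]
    chroms = sorted({v.chrom for v in cohort.variants}, key=_chrom_sort_key)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    if cohort.dr2 is not None:
        lines.append('##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation dosage R-squared">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples))
    for i, v in enumerate(cohort.variants):
        info = "." if cohort.dr2 is None else f"DR2={cohort.dr2[i]:.4g}"
        gts = []
        for j in range(len(cohort.samples)):
            a, b = cohort.haplotypes[j, i]
            gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts))
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    if ped_path is not None:
        write_pedigree(cohort.pedigree, ped_path)


def write_pedigree(pedigree: Mapping[str, tuple[str, str | None]], path: str | Path) -> None:
    rows = [
        {"child": c, "mother": m, "father": "NA" if f is None else f}
        for c, (m, f) in pedigree.items()
    ]
    pd.DataFrame(rows, columns=["child", "mother", "father"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "p_value", "trait"]


def read_summary_stats(path: str | Path, trait: str) -> pd.DataFrame:
    """Read the rows of a summary-statistics TSV for one trait.

    Returns a DataFrame with SUMSTAT_COLUMNS; alleles are upper-cased and
    p-values validated to lie in (0, 1].
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str}, float_precision="round_trip")
    if missing := set(SUMSTAT_COLUMNS) - set(df.columns):
        raise ValidationError(f"summary stats missing columns {sorted(missing)}")
    bad_trait = set(df["trait"]) - set(TRAITS)
    if bad_trait:
        raise ValidationError(f"unknown trait labels in table: {sorted(bad_trait)}")
    df = df[df["trait"] == trait].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ValidationError("p_value outside (0, 1]")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValidationError("effect_allele equals other_allele")
    return df[SUMSTAT_COLUMNS].reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def match_alleles(sumstats: pd.DataFrame, cohort: PhasedTrioCohort) -> pd.DataFrame:
    """Resolve summary-stat alleles against cohort (ref, alt).

    Adds ``beta_alt`` — the effect size per alt-allele copy (sign-flipped when
    the effect allele is the ref).  Strand flips are never attempted; rows
    that match neither orientation are dropped with a warning (palindromic
    SNPs are called out, since a strand flip there is undetectable).
    """
    vmap = {v.id: v for v in cohort.variants}
    rows = []
    for r in sumstats.itertuples():
        v = vmap.get(r.variant_id)
        if v is None:
            continue
        if (r.effect_allele, r.other_allele) == (v.alt, v.ref):
            beta_alt = r.beta
        elif (r.effect_allele, r.other_allele) == (v.ref, v.alt):
            beta_alt = -r.beta
        else:
            kind = "palindromic " if v.is_palindromic else ""
            logger.warning(
                "dropping %svariant %s: sumstat alleles %s/%s match neither cohort orientation %s/%s",
                kind, r.variant_id, r.effect_allele, r.other_allele, v.ref, v.alt,
            )
            continue
        rows.append({**r._asdict(), "beta_alt": beta_alt})
    out = pd.DataFrame(rows, columns=SUMSTAT_COLUMNS + ["beta_alt", "Index"])
    return out.drop(columns=["Index"], errors="ignore").reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotypes + BP observations
# ---------------------------------------------------------------------------

PHENO_COLUMNS = [
    "pair_id", "pre_pregnancy_bmi", "birth_weight", "placental_weight",
    "gestational_age_at_delivery", "fetal_sex", "parity", "hypertension_flag",
]
BP_COLUMNS = ["pair_id", "gestational_week", "sbp", "dbp"]


def read_phenotypes(pheno_path: str | Path, bp_path: str | Path) -> list[PhenotypeRecord]:
    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"pair_id": str}, float_precision="round_trip")
    bp = pd.read_csv(bp_path, sep="\t", dtype={"pair_id": str}, float_precision="round_trip")
    for df, cols, name in ((pheno, PHENO_COLUMNS, "phenotype"), (bp, BP_COLUMNS, "BP")):
        if missing := set(cols) - set(df.columns):
            raise ValidationError(f"{name} table missing columns {sorted(missing)}")
    bp_by_pair = {
        pid: tuple(sorted((r.gestational_week, r.sbp, r.dbp) for r in grp.itertuples()))
        for pid, grp in bp.groupby("pair_id")
    }
    return [
        PhenotypeRecord(
            pair_id=r.pair_id,
            pre_pregnancy_bmi=r.pre_pregnancy_bmi,
            bp_obs=bp_by_pair.get(r.pair_id, ()),
            birth_weight=r.birth_weight,
            placental_weight=r.placental_weight,
            gestational_age_at_delivery=r.gestational_age_at_delivery,
            fetal_sex=r.fetal_sex,
            parity=r.parity,
            hypertension_flag=r.hypertension_flag,
        )
        for r in pheno.itertuples()
    ]


def write_phenotypes(records: Sequence[PhenotypeRecord], pheno_path: str | Path, bp_path: str | Path) -> None:
    pheno_rows, bp_rows = [], []
    for rec in records:
        pheno_rows.append({c: getattr(rec, c if c != "gestational_age_at_delivery" else "gestational_age_at_delivery") for c in PHENO_COLUMNS})
        for week, sbp, dbp in rec.bp_obs:
            bp_rows.append({"pair_id": rec.pair_id, "gestational_week": week, "sbp": sbp, "dbp": dbp})
    pd.DataFrame(pheno_rows, columns=PHENO_COLUMNS).to_csv(pheno_path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(bp_rows, columns=BP_COLUMNS).to_csv(bp_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reference chart, ultrasound, annotation
# ---------------------------------------------------------------------------

CHART_COLUMNS = ["week", "fetal_sex", "parity", "bw_mean", "bw_sd", "pw_mean", "pw_sd"]


def read_reference_chart(path: str | Path) -> ReferenceChart:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if missing := set(CHART_COLUMNS) - set(df.columns):
        raise ValidationError(f"chart missing columns {sorted(missing)}")
    return ReferenceChart(df[CHART_COLUMNS])


def write_reference_chart(chart: ReferenceChart, path: str | Path) -> None:
    chart.table[CHART_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


US_COLUMNS = ["pair_id", "gestational_week", "efw"]


def read_ultrasound(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """pair_id -> [(week, efw g), ...], weeks strictly increasing, efw > 0."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str}, float_precision="round_trip")
    if missing := set(US_COLUMNS) - set(df.columns):
        raise ValidationError(f"ultrasound table missing columns {sorted(missing)}")
    if (df["efw"] <= 0).any():
        raise ValidationError("EFW must be positive")
    out: dict[str, list[tuple[float, float]]] = {}
    for pid, grp in df.groupby("pair_id", sort=False):
        obs = [(r.gestational_week, r.efw) for r in grp.itertuples()]
        weeks = [w for w, _ in obs]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValidationError(f"{pid}: ultrasound weeks not strictly increasing")
        out[pid] = obs
    return out


def write_ultrasound(series: Mapping[str, Sequence[tuple[float, float]]], path: str | Path) -> None:
    rows = [
        {"pair_id": pid, "gestational_week": w, "efw": e}
        for pid, obs in series.items()
        for w, e in obs
    ]
    pd.DataFrame(rows, columns=US_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.17g")


ANNOTATION_COLUMNS = ["variant_id", "vasc_class", "sbp_increasing_allele", "trait_memberships", "dbp_discordant"]


def read_annotation(path: str | Path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "trait_memberships": str})
    if missing := set(ANNOTATION_COLUMNS) - set(df.columns):
        raise ValidationError(f"annotation table missing columns {sorted(missing)}")
    out: dict[str, AnnotationRecord] = {}
    for r in df.itertuples():
        traits = frozenset(t for t in str(r.trait_memberships).split(",") if t)
        out[r.variant_id] = AnnotationRecord(
            variant_id=r.variant_id,
            vasc_class=r.vasc_class,
            sbp_increasing_allele=str(r.sbp_increasing_allele).upper(),
            trait_memberships=traits,
            dbp_discordant=bool(r.dbp_discordant),
        )
    return out


def write_annotation(records: Mapping[str, AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "variant_id": a.variant_id,
            "vasc_class": a.vasc_class,
            "sbp_increasing_allele": a.sbp_increasing_allele,
            "trait_memberships": ",".join(sorted(a.trait_memberships)),
            "dbp_discordant": a.dbp_discordant,
        }
        for a in records.values()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged fixtures (synthetic stand-ins for non-deposited supplementary panels)
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_panel41() -> dict[str, AnnotationRecord]:
    """Synthetic 41-SNP BP-associated panel (SBP/DBP/MAP/PP, genome-wide
    significant), matching the published class sizes 18/12/11 and seven
    DBP-discordant PP-associated SNPs."""
    return read_annotation(_data_path("bp41_annotation_synthetic.tsv"))


def load_panel67() -> dict[str, AnnotationRecord]:
    """Synthetic 67-SNP SBP panel (p < 1e-6), class sizes 21/30/16."""
    return read_annotation(_data_path("sbp67_annotation_synthetic.tsv"))


def load_default_chart() -> ReferenceChart:
    """Synthetic perinatal reference chart, weeks 34-42 x sex x parity."""
    return read_reference_chart(_data_path("reference_chart_synthetic.tsv"))
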