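"""Parental-origin inference and haplotype allele counts.

For each mother–child pair and SNP, the child's alleles are split into the
maternal transmitted and paternal transmitted copies, and the mother's
untransmitted allele is identified.  When either mother or child is
homozygous the split follows from Mendelian logic alone; when both are
heterozygous the child haplotype sharing the longer exact flanking match
with a maternal haplotype (within a +-window of surrounding variants) is
taken as maternal — a local-haplotype-sharing rule.  Exact ties over the
full window are left unresolved and excluded from all three counts.

The three per-pair scores are the unweighted sums of BP-increasing alleles
on (1) the maternal transmitted, (2) the maternal non-transmitted and
(3) the paternal transmitted haplotype.  The non-transmitted count indexes
purely environmental (intrauterine) maternal influence, since those alleles
never reach the child.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PhasedTrioCohort

DEFAULT_WINDOW = 25


@dataclass(frozen=True)
class TransmissionCall:
    """Resolved allele attribution at one site (alleles are 0/1 alt counts)."""

    maternal_transmitted: int | None
    maternal_non_transmitted: int | None
    paternal_transmitted: int | None
    resolved: bool
    method: str  # homozygote | haplotype-sharing | unresolved


def _flank_match(child_hap: np.ndarray, mother_hap: np.ndarray, site: int, window: int) -> int:
    """Length of the exact contiguous match around ``site`` (inclusive),
    truncated at ``window`` variants on each side; 0 if the focal alleles
    differ."""
    if child_hap[site] != mother_hap[site]:
        return 0
    length = 1
    lo = max(0, site - window)
    for j in range(site - 1, lo - 1, -1):
        if child_hap[j] != mother_hap[j]:
            break
        length += 1
    hi = min(len(child_hap) - 1, site + window)
    for j in range(site + 1, hi + 1):
        if child_hap[j] != mother_hap[j]:
            break
        length += 1
    return length


def infer_transmission(
    cohort: PhasedTrioCohort,
    child: str,
    variant_id: str,
    window: int = DEFAULT_WINDOW,
) -> TransmissionCall:
    """Attribute the child's two alleles at ``variant_id`` to the parents.

    Requires phased mother and child; the father's genotypes are never
    consulted — the paternal transmitted allele is simply the child allele
    not attributed to the mother.
    """
    site = cohort.variant_index(variant_id)
    mother, _ = cohort.pedigree[child]
    mh = cohort.haplotypes[cohort.sample_index(mother)]  # (n_variants, 2)
    ch = cohort.haplotypes[cohort.sample_index(child)]

    m0, m1 = int(mh[site, 0]), int(mh[site, 1])
    c0, c1 = int(ch[site, 0]), int(ch[site, 1])
    if min(m0, m1, c0, c1) < 0:
        return TransmissionCall(None, None, None, False, "unresolved")

    if m0 == m1:  # mother homozygous: transmitted allele known outright
        mt = m0
        if c0 == c1 and c0 != mt:
            return TransmissionCall(None, None, None, False, "unresolved")  # Mendelian conflict
        pt = c1 if c0 == mt else c0
        return TransmissionCall(mt, m0, pt, True, "homozygote")
    if c0 == c1:  # child homozygous, mother heterozygous
        mt = c0
        return TransmissionCall(mt, 1 - mt, c0, True, "homozygote")

    # double heterozygote: local haplotype sharing
    share = [
        max(
            _flank_match(ch[:, h], mh[:, 0], site, window),
            _flank_match(ch[:, h], mh[:, 1], site, window),
        )
        for h in (0, 1)
    ]
    if share[0] == share[1]:
        return TransmissionCall(None, None, None, False, "unresolved")
    h_maternal = int(np.argmax(share))
    mt = int(ch[site, h_maternal])
    pt = int(ch[site, 1 - h_maternal])
    return TransmissionCall(mt, 1 - mt, pt, True, "haplotype-sharing")


def haplotype_scores(
    cohort: PhasedTrioCohort,
    counted_alleles: dict[str, str],
    variant_ids: list[str],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Per-pair maternal-transmitted / non-transmitted / paternal-transmitted
    counts of the counted (BP-increasing) allele over ``variant_ids``.

    Unresolved sites are excluded from all three sums and tallied in
    ``n_unresolved``.  Rows are indexed by child sample id and carry the
    mother id and a father-present flag.
    """
    vmap = {v.id: v for v in cohort.variants}
    rows = []
    for child in cohort.children:
        mother, father = cohort.pedigree[child]
        mt = mnt = pt = 0
        n_res = n_unres = 0
        for vid in variant_ids:
            call = infer_transmission(cohort, child, vid, window)
            if not call.resolved:
                n_unres += 1
                continue
            n_res += 1
            v = vmap[vid]
            counted = counted_alleles[vid]
            inc = 1 if counted == v.alt else 0  # allele code of the counted allele
            mt += int(call.maternal_transmitted == inc)
            mnt += int(call.maternal_non_transmitted == inc)
            pt += int(call.paternal_transmitted == inc)
        rows.append(
            {
                "child": child,
                "mother": mother,
                "father_present": father is not None,
                "mt_count": mt,
                "mnt_count": mnt,
                "pt_count": pt,
                "n_resolved": n_res,
                "n_unresolved": n_unres,
            }
        )
    return pd.DataFrame(rows).set_index("child")
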