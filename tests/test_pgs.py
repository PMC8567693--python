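"""QC filters, LD clumping vs a brute-force oracle, thresholded scoring,
allele orientation, unweighted scores and pleiotropy exclusion."""

import numpy as np
import pandas as pd
import pytest

from placentamed import pgs
from placentamed.io_formats import PhasedTrioCohort, Variant, load_panel41, load_panel67
from placentamed.synthetic import SimulationConfig, simulate_cohort


def _toy_cohort(haps, variants, n_trios=None):
    """haps: (n_samples, n_variants, 2); samples are all mothers."""
    n = haps.shape[0]
    samples = [f"M{i}" for i in range(n)]
    return PhasedTrioCohort(
        variants=variants,
        samples=samples,
        roles={s: "mother" for s in samples},
        pedigree={},
        haplotypes=np.asarray(haps, dtype=np.int8),
    )


class TestQC:
    def test_perfect_hwe_retained(self):
        assert pgs.hwe_chi2_p(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_variant_removed(self, small_bundle):
        cohort = small_bundle.cohort
        h = cohort.haplotypes.copy()
        h[:, 0, :] = 0  # force monomorphic
        mono = PhasedTrioCohort(
            variants=list(cohort.variants), samples=list(cohort.samples),
            roles=dict(cohort.roles), pedigree=dict(cohort.pedigree), haplotypes=h,
        )
        filtered, report = pgs.qc_filter(mono)
        vid = cohort.variants[0].id
        assert report.loc[vid, "maf"] and report.loc[vid, "excluded"]
        assert vid not in {v.id for v in filtered.variants}

    def test_planted_failures_exactly_removed(self, small_bundle):
        cohort = small_bundle.cohort
        h = cohort.haplotypes.copy()
        planted = list(range(0, 30, 3))  # 10 variants
        for k, j in enumerate(planted):
            if k % 2 == 0:
                h[: int(0.1 * h.shape[0]), j, :] = -1        # low call rate
            else:
                h[:, j, :] = 0                               # monomorphic
        dr2 = np.ones(len(cohort.variants))
        broken = PhasedTrioCohort(
            variants=list(cohort.variants), samples=list(cohort.samples),
            roles=dict(cohort.roles), pedigree=dict(cohort.pedigree),
            haplotypes=h, dr2=dr2,
        )
        _, report = pgs.qc_filter(broken)
        expected = {cohort.variants[j].id for j in planted}
        assert set(report.index[report["excluded"]]) == expected

    def test_dr2_filter(self, small_bundle):
        cohort = small_bundle.cohort
        dr2 = np.ones(len(cohort.variants))
        dr2[5] = 0.5
        c = PhasedTrioCohort(
            variants=list(cohort.variants), samples=list(cohort.samples),
            roles=dict(cohort.roles), pedigree=dict(cohort.pedigree),
            haplotypes=cohort.haplotypes.copy(), dr2=dr2,
        )
        filtered, report = pgs.qc_filter(c)
        assert report["dr2"].sum() == 1
        assert cohort.variants[5].id not in {v.id for v in filtered.variants}

    def test_empty_after_qc_raises(self):
        variants = [Variant(id="rs1", chrom="1", pos=100, ref="A", alt="G")]
        haps = np.zeros((4, 1, 2))  # monomorphic -> removed -> empty
        with pytest.raises(pgs.QCError):
            pgs.qc_filter(_toy_cohort(haps, variants))


def _sumstats(variants, pvals, betas=None):
    return pd.DataFrame(
        {
            "variant_id": [v.id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.alt for v in variants],
            "other_allele": [v.ref for v in variants],
            "beta": betas if betas is not None else np.ones(len(variants)) * 0.1,
            "p_value": pvals,
            "trait": "SBP",
        }
    )


def _brute_force_clump(sumstats, dosages, positions, chroms, r2_thr, window_bp):
    """Independent oracle: explicit greedy clumping with per-pair numpy r^2."""
    order = sumstats.sort_values(["p_value", "chrom", "pos"], kind="mergesort")["variant_id"].tolist()
    removed = set()
    kept = []
    for vid in order:
        if vid in removed:
            continue
        kept.append(vid)
        for other in order:
            if other == vid or other in removed or other in kept:
                continue
            if chroms[other] != chroms[vid] or abs(positions[other] - positions[vid]) > window_bp:
                continue
            a, b = dosages[vid], dosages[other]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            if np.corrcoef(a, b)[0, 1] ** 2 >= r2_thr:
                removed.add(other)
    return kept


class TestClumping:
    def test_correlated_pair_keeps_smaller_p(self):
        variants = [
            Variant(id="rs1", chrom="1", pos=10_000, ref="A", alt="G"),
            Variant(id="rs2", chrom="1", pos=20_000, ref="C", alt="T"),
        ]
        col = np.random.default_rng(0).integers(0, 2, (20, 1, 2))
        haps = np.concatenate([col, col], axis=1)  # r^2 = 1
        cohort = _toy_cohort(haps, variants)
        ss = _sumstats(variants, [1e-8, 1e-6])
        assert pgs.ld_clump(ss, cohort) == ["rs1"]

    def test_independent_pair_both_kept(self, rng):
        variants = [
            Variant(id="rs1", chrom="1", pos=10_000, ref="A", alt="G"),
            Variant(id="rs2", chrom="1", pos=20_000, ref="C", alt="T"),
        ]
        haps = rng.integers(0, 2, (500, 2, 2))
        cohort = _toy_cohort(haps, variants)
        ss = _sumstats(variants, [1e-8, 1e-6])
        assert set(pgs.ld_clump(ss, cohort)) == {"rs1", "rs2"}

    def test_matches_brute_force_on_block_structure(self):
        cfg = SimulationConfig(seed=55, n_trios=60, n_blocks=3, block_size=5,
                               within_block_r2=0.9, n_causal=3)
        b = simulate_cohort(cfg)
        ss = b.sumstats["SBP"]
        result = pgs.ld_clump(ss, b.cohort)
        dos = b.cohort.dosages(b.cohort.mothers)
        dosages = {v.id: dos[v.id].to_numpy() for v in b.cohort.variants}
        positions = {v.id: v.pos for v in b.cohort.variants}
        chroms = {v.id: v.chrom for v in b.cohort.variants}
        oracle = _brute_force_clump(ss, dosages, positions, chroms, 0.1, 1_000_000)
        assert set(result) == set(oracle)

    def test_no_retained_pair_violates_r2(self, small_bundle):
        result = pgs.ld_clump(small_bundle.sumstats["SBP"], small_bundle.cohort)
        dos = small_bundle.cohort.dosages(small_bundle.cohort.mothers)
        pos = {v.id: (v.chrom, v.pos) for v in small_bundle.cohort.variants}
        kept = list(result)
        for i, a in enumerate(kept):
            for b_ in kept[i + 1:]:
                ca, pa = pos[a]
                cb, pb = pos[b_]
                if ca == cb and abs(pa - pb) <= 1_000_000:
                    r2 = np.corrcoef(dos[a], dos[b_])[0, 1] ** 2
                    assert r2 < 0.1

    def test_missing_variant_raises(self, small_bundle):
        ss = small_bundle.sumstats["SBP"].copy()
        ss.loc[0, "variant_id"] = "rs_absent"
        with pytest.raises(KeyError):
            pgs.ld_clump(ss, small_bundle.cohort)


class TestScoring:
    def test_raw_score_arithmetic(self):
        variants = [
            Variant(id=f"rs{i}", chrom="1", pos=10_000 * (i + 1), ref="A", alt="G")
            for i in range(3)
        ]
        # one mother with alt dosages [0, 1, 2]
        haps = np.array([[[0, 0], [0, 1], [1, 1]], [[0, 0], [0, 0], [0, 0]]])
        cohort = _toy_cohort(haps, variants)
        ss = _sumstats(variants, [1e-9] * 3, betas=[0.1, -0.2, 0.3])
        res = pgs.threshold_and_score(ss, cohort, [v.id for v in variants], (1e-6,))
        # oriented to increasing alleles: 0*0.1 + (2-1)*0.2 + 2*0.3 = 0.8;
        # the alt-dosage-weighted equivalent is 0.8 - 2*0.2 = 0.4
        assert res[1e-6].raw_score.iloc[0] == pytest.approx(0.8)
        assert res[1e-6].raw_score.iloc[0] - 2 * 0.2 == pytest.approx(0.4)

    def test_zero_betas_flagged_degenerate_not_nan(self, small_bundle):
        ss = small_bundle.sumstats["SBP"].copy()
        ss["beta"] = 0.0
        clumped = pgs.ld_clump(ss, small_bundle.cohort)
        res = pgs.threshold_and_score(ss, small_bundle.cohort, clumped, (1.0,))
        r = res[1.0]
        assert r.degenerate
        assert not r.z_score.isna().any()

    def test_empty_threshold_flagged_not_error(self, small_bundle):
        ss = small_bundle.sumstats["SBP"]
        clumped = pgs.ld_clump(ss, small_bundle.cohort)
        res = pgs.threshold_and_score(ss, small_bundle.cohort, clumped, (1e-300,))
        assert res[1e-300].empty

    def test_score_recovers_true_liability(self, small_bundle):
        ss = small_bundle.sumstats["SBP"]
        clumped = pgs.ld_clump(ss, small_bundle.cohort)
        res = pgs.threshold_and_score(ss, small_bundle.cohort, clumped, (1e-6,))
        z = res[1e-6].z_score
        truth = small_bundle.truth
        mothers = [f"M{int(p[1:]):04d}" for p in truth.pair_ids]
        r = np.corrcoef(z.loc[mothers], truth.pgs_z)[0, 1]
        assert abs(r) > 0.9

    def test_z_scores_invariant_to_allele_label_swap(self, small_bundle):
        ss = small_bundle.sumstats["SBP"].head(20).copy()
        ids = list(ss["variant_id"])
        swapped = ss.copy()
        swapped["effect_allele"], swapped["other_allele"] = ss["other_allele"], ss["effect_allele"]
        swapped["beta"] = -ss["beta"]
        r1 = pgs.threshold_and_score(ss, small_bundle.cohort, ids, (1.0,))[1.0]
        r2 = pgs.threshold_and_score(swapped, small_bundle.cohort, ids, (1.0,))[1.0]
        np.testing.assert_allclose(r1.z_score, r2.z_score, atol=1e-9)

    def test_threshold_nesting(self, small_bundle):
        ss = small_bundle.sumstats["SBP"]
        clumped = pgs.ld_clump(ss, small_bundle.cohort)
        res = pgs.threshold_and_score(ss, small_bundle.cohort, clumped)
        thresholds = sorted(res)
        for t1, t2 in zip(thresholds, thresholds[1:]):
            assert set(res[t1].variant_ids) <= set(res[t2].variant_ids)

    def test_z_score_moments(self, small_bundle):
        ss = small_bundle.sumstats["SBP"]
        clumped = pgs.ld_clump(ss, small_bundle.cohort)
        r = pgs.threshold_and_score(ss, small_bundle.cohort, clumped, (1e-4,))[1e-4]
        assert r.z_score.mean() == pytest.approx(0.0, abs=1e-9)
        assert r.z_score.var(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestOrientationAndSubscores:
    def test_counted_allele_is_sbp_increasing(self):
        panel = load_panel41()
        counted = pgs.orient_sbp_increasing(panel, list(panel))
        for vid, allele in counted.items():
            assert allele == panel[vid].sbp_increasing_allele

    def test_discordant_variants_still_counted_on_sbp_allele(self):
        panel = load_panel41()
        disc = [v for v, a in panel.items() if a.dbp_discordant]
        assert len(disc) == 7
        counted = pgs.orient_sbp_increasing(panel, disc)
        assert all(counted[v] == panel[v].sbp_increasing_allele for v in disc)

    def test_missing_annotation_listed(self):
        panel = load_panel41()
        with pytest.raises(KeyError, match="rs_missing"):
            pgs.orient_sbp_increasing(panel, ["rs_missing"])

    def test_unweighted_score_bounds_and_partition(self, small_bundle):
        cohort = small_bundle.cohort
        ids = [v.id for v in cohort.variants[:12]]
        counted = {v.id: v.alt for v in cohort.variants[:12]}
        full = pgs.unweighted_score(cohort, counted, ids)
        assert ((full >= 0) & (full <= 2 * len(ids))).all()
        part1 = pgs.unweighted_score(cohort, counted, ids[:5])
        part2 = pgs.unweighted_score(cohort, counted, ids[5:])
        pd.testing.assert_series_equal(full, part1 + part2)

    def test_homozygous_extremes(self):
        variants = [
            Variant(id=f"rs{i}", chrom="1", pos=1000 * (i + 1), ref="A", alt="G")
            for i in range(5)
        ]
        haps = np.stack([np.ones((5, 2)), np.zeros((5, 2))]).astype(np.int8)
        cohort = _toy_cohort(haps, variants)
        counted = {v.id: v.alt for v in variants}
        scores = pgs.unweighted_score(cohort, counted, [v.id for v in variants])
        assert scores.iloc[0] == 10
        assert scores.iloc[1] == 0

    def test_empty_subset_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            pgs.unweighted_score(small_bundle.cohort, {}, [])


class TestSubdivision:
    def test_panel41_class_sizes(self):
        panel = load_panel41()
        parts = pgs.subdivide_by_class(panel, list(panel))
        assert (len(parts["vasculature-related"]), len(parts["unlikely related"]),
                len(parts["unknown"])) == (18, 12, 11)

    def test_panel67_class_sizes(self):
        panel = load_panel67()
        parts = pgs.subdivide_by_class(panel, list(panel))
        assert (len(parts["vasculature-related"]), len(parts["unlikely related"]),
                len(parts["unknown"])) == (21, 30, 16)

    def test_partition_is_disjoint_and_exhaustive(self):
        panel = load_panel41()
        parts = pgs.subdivide_by_class(panel, list(panel))
        all_ids = sum(parts.values(), [])
        assert sorted(all_ids) == sorted(panel)

    def test_empty_input(self):
        parts = pgs.subdivide_by_class(load_panel41(), [])
        assert all(len(v) == 0 for v in parts.values())

    def test_unlabeled_variant_raises(self):
        with pytest.raises(KeyError):
            pgs.subdivide_by_class(load_panel41(), ["rs_unknown"])


class TestPleiotropyExclusion:
    def _aux(self, small_bundle):
        return {t: small_bundle.sumstats[t] for t in ("BMI", "T2D", "HbA1c")}

    def test_no_hits_leaves_set_unchanged(self, small_bundle):
        ids = [v.id for v in small_bundle.cohort.variants[:10]]
        aux = {t: df.assign(p_value=0.5) for t, df in self._aux(small_bundle).items()}
        assert pgs.exclude_pleiotropic(ids, aux, 1e-4) == ids

    def test_planted_hit_removed_at_all_thresholds(self, small_bundle):
        ids = [v.id for v in small_bundle.cohort.variants[:10]]
        aux = self._aux(small_bundle)
        bmi = aux["BMI"].copy()
        bmi.loc[bmi["variant_id"] == ids[3], "p_value"] = 1e-9
        aux["BMI"] = bmi
        for thr in (1e-8, 1e-6, 1e-4):
            assert ids[3] not in pgs.exclude_pleiotropic(ids, aux, thr)

    def test_threshold_monotonicity(self, small_bundle):
        ids = [v.id for v in small_bundle.cohort.variants]
        aux = self._aux(small_bundle)
        kept = {thr: set(pgs.exclude_pleiotropic(ids, aux, thr)) for thr in (1e-8, 1e-6, 1e-4)}
        assert kept[1e-8] >= kept[1e-6] >= kept[1e-4]
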