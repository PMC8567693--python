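"""Generator contracts: LD structure, Mendelian transmission, mediation
calibration, heritability targets, growth-curve truth, determinism."""

import numpy as np
import pandas as pd
import pytest

from placentamed import synthetic
from placentamed.synthetic import (
    ConfigError,
    SimulationConfig,
    sample_dosages,
    simulate_cohort,
    simulate_haplotype_pool,
    simulate_trait,
    simulate_trios,
    write_cohort,
)


def _adjacent_r2(pool, config):
    out = []
    h = pool.haplotypes.astype(float)
    for b in range(config.n_blocks):
        for j in range(config.block_size - 1):
            k = b * config.block_size + j
            r = np.corrcoef(h[:, k], h[:, k + 1])[0, 1]
            out.append(r * r)
    return np.array(out)


class TestHaplotypePool:
    def test_independent_blocks_have_near_zero_adjacent_r2(self):
        cfg = SimulationConfig(seed=1, n_blocks=10, block_size=5, n_causal=5, within_block_r2=0.0,
                               pool_size=2000, maf_range=(0.2, 0.4))
        r2 = _adjacent_r2(simulate_haplotype_pool(cfg), cfg)
        assert r2.mean() < 0.05

    def test_adjacent_r2_tracks_target(self):
        cfg = SimulationConfig(seed=2, n_blocks=10, block_size=5, n_causal=5, within_block_r2=0.8,
                               pool_size=2000, maf_range=(0.2, 0.4))
        r2 = _adjacent_r2(simulate_haplotype_pool(cfg), cfg)
        assert abs(r2.mean() - 0.8) < 0.1

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(seed=3, n_blocks=5, block_size=4, n_causal=3)
        p1 = simulate_haplotype_pool(cfg)
        p2 = simulate_haplotype_pool(cfg)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)

    def test_infeasible_r2_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, within_block_r2=1.5)


class TestTrios:
    def test_mendelian_consistency_everywhere(self, small_bundle):
        cohort = small_bundle.cohort
        for child in cohort.children:
            mother, father = cohort.pedigree[child]
            ch = cohort.haplotypes[cohort.sample_index(child)]
            mh = cohort.haplotypes[cohort.sample_index(mother)]
            fh = cohort.haplotypes[cohort.sample_index(father)]
            for j in range(len(cohort.variants)):
                assert ch[j, 0] in mh[j] or ch[j, 1] in mh[j]
                assert set(ch[j]) <= set(mh[j]) | set(fh[j])

    def test_child_first_haplotype_is_exact_maternal_copy(self, small_bundle):
        cohort, truth = small_bundle.cohort, small_bundle.truth
        for i, child in enumerate(cohort.children):
            mother, _ = cohort.pedigree[child]
            ch = cohort.haplotypes[cohort.sample_index(child)][:, 0]
            mh = cohort.haplotypes[cohort.sample_index(mother)][:, truth.maternal_transmitted[i]]
            np.testing.assert_array_equal(ch, mh)

    def test_child_allele_frequencies_match_pool(self):
        cfg = SimulationConfig(seed=4, n_trios=400, n_blocks=10, block_size=3, n_causal=5, pool_size=5000)
        pool = simulate_haplotype_pool(cfg)
        cohort, _ = simulate_trios(pool, cfg)
        cidx = [cohort.sample_index(s) for s in cohort.children]
        child_af = cohort.haplotypes[cidx].mean(axis=(0, 2))
        pool_af = pool.haplotypes.mean(axis=0)
        se = np.sqrt(pool_af * (1 - pool_af) / (2 * cfg.n_trios))
        assert (np.abs(child_af - pool_af) <= 3 * se + 1e-9).mean() > 0.98

    def test_zero_trios_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, n_trios=0)


class TestPhenotypes:
    def test_null_path_gives_null_mediator_association(self):
        ests = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_blocks=15, block_size=3, n_causal=10, a=0.0)
            b = simulate_cohort(cfg)
            t = b.truth
            ests.append(np.polyfit(t.pgs_z, t.mediator_z, 1)[0])
        ests = np.array(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean()) < 2 * se + 0.01

    def test_calibrated_product_of_coefficients(self):
        # generating paths are the published point estimates; on a single
        # n=93 draw the product-of-coefficients estimate should fall within
        # ~2 SE of a*b = -0.262
        cfg = SimulationConfig(seed=7, n_blocks=15, block_size=3, n_causal=10)
        t = simulate_cohort(cfg).truth
        a_hat = np.polyfit(t.pgs_z, t.mediator_z, 1)[0]
        X = np.column_stack([np.ones_like(t.pgs_z), t.pgs_z, t.mediator_z])
        b_hat = np.linalg.lstsq(X, t.outcome_z, rcond=None)[0][2]
        assert abs(a_hat * b_hat - (-0.262)) < 0.17  # ~2 SE at n = 93

    def test_h2_target_recovered_at_large_n(self):
        cfg = SimulationConfig(seed=11, n_blocks=60, block_size=2, n_causal=60, pool_size=4000)
        pool = simulate_haplotype_pool(cfg)
        cohort, truth = simulate_trios(pool, cfg)
        synthetic.simulate_phenotypes(cohort, truth, pool, cfg)
        rng = np.random.default_rng(5)
        dos = sample_dosages(pool, 10_000, rng).astype(float)
        liab = dos @ truth.gen_beta_alt
        trait = simulate_trait(liab, cfg.h2["SBP"], rng)
        r2 = np.corrcoef(liab, trait)[0, 1] ** 2
        assert abs(r2 - 0.0569) < 0.01

    def test_variance_bookkeeping_error(self):
        with pytest.raises(ConfigError):
            cfg = SimulationConfig(seed=1, n_blocks=10, n_causal=5, a=0.5, b=0.9, c_direct=0.5)
            simulate_cohort(cfg)

    def test_chart_backtransform_is_exact_inverse(self, small_bundle):
        from placentamed.phenotype import chart_adjust

        truth = small_bundle.truth
        z = {p: i for i, p in enumerate(truth.pair_ids)}
        for rec in small_bundle.phenotypes[:20]:
            adj = chart_adjust(rec, small_bundle.chart)
            i = z[rec.pair_id]
            assert adj.bw_z == pytest.approx(truth.outcome_z[i], abs=1e-9)
            assert adj.pw_z == pytest.approx(truth.mediator_z[i], abs=1e-9)


class TestUltrasound:
    def test_zero_link_decouples_mediator_and_velocity(self):
        cfg = SimulationConfig(seed=21, n_trios=200, n_blocks=10, block_size=3,
                               n_causal=8, velocity_link=0.0)
        b = simulate_cohort(cfg)
        v34 = b.truth.true_velocity.loc[34].to_numpy()
        r = np.corrcoef(b.truth.mediator_z, v34)[0, 1]
        assert abs(r) < 2 / np.sqrt(cfg.n_trios)

    def test_positive_link_gives_positive_late_velocity_correlation(self):
        # a smaller placenta (lower mediator z) slows late-gestation growth
        cfg = SimulationConfig(seed=22, n_blocks=10, block_size=3, n_causal=8,
                               velocity_link=30.0)
        b = simulate_cohort(cfg)
        v36 = b.truth.true_velocity.loc[36].to_numpy()
        assert np.corrcoef(b.truth.mediator_z, v36)[0, 1] > 0.3

    def test_noiseless_observations_lie_on_true_curve(self):
        from scipy.interpolate import PchipInterpolator

        cfg = SimulationConfig(seed=23, n_blocks=10, block_size=3, n_causal=8, efw_noise=0.0)
        b = simulate_cohort(cfg)
        grid = b.truth.true_efw.index.to_numpy(dtype=float)
        for pid, obs in list(b.ultrasound.items())[:10]:
            curve = PchipInterpolator(grid, b.truth.true_efw[pid].to_numpy())
            for w, e in obs:
                assert e == pytest.approx(float(curve(w)), rel=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=1, n_obs_range=(3, 5))


class TestDeterminism:
    def test_identical_seed_writes_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=31, n_blocks=6, block_size=3, n_causal=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_cohort(simulate_cohort(cfg), d1)
        p2 = write_cohort(simulate_cohort(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
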