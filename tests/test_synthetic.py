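"""Tests for the LD-aware region and cohort simulators."""

import numpy as np
import pytest

from colocus.eqtl import fit_cis_eqtl
from colocus.synthetic import (
    HaplotypePanel,
    ScenarioSpec,
    ld_r2,
    pick_low_ld_pair,
    pick_tagging_snp,
    simulate_case_control_gwas,
    simulate_eqtl_study,
    simulate_haplotype_panel,
)


class TestHaplotypePanel:
    def test_determinism(self):
        a = simulate_haplotype_panel(20, 100, rho=0.7, seed=5)
        b = simulate_haplotype_panel(20, 100, rho=0.7, seed=5)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.freqs, b.freqs)

    def test_different_seed_differs(self):
        a = simulate_haplotype_panel(20, 100, seed=5)
        b = simulate_haplotype_panel(20, 100, seed=6)
        assert not np.array_equal(a.alleles, b.alleles)

    def test_rho_zero_independence(self):
        panel = simulate_haplotype_panel(2, 10_000, rho=0.0, seed=1)
        r2 = ld_r2(panel.alleles[:, 0], panel.alleles[:, 1])
        assert r2 < 0.01

    def test_single_snp_frequency_concentration(self):
        panel = simulate_haplotype_panel(1, 20_000, maf_range=(0.3, 0.3), seed=2)
        assert panel.freqs[0] == pytest.approx(0.3, abs=0.02)

    def test_high_rho_builds_ld(self):
        panel = simulate_haplotype_panel(2, 10_000, rho=0.95, seed=3)
        assert ld_r2(panel.alleles[:, 0], panel.alleles[:, 1]) > 0.5

    @pytest.mark.parametrize("kwargs", [
        dict(Q=0, n_hap=10), dict(Q=5, n_hap=1),
        dict(Q=5, n_hap=10, maf_range=(0.0, 0.3)),
        dict(Q=5, n_hap=10, maf_range=(0.4, 0.2)),
        dict(Q=5, n_hap=10, rho=1.0),
    ])
    def test_invalid_args(self, kwargs):
        with pytest.raises(ValueError):
            simulate_haplotype_panel(**{**dict(Q=5, n_hap=10), **kwargs})

    def test_freqs_invariant_enforced(self):
        with pytest.raises(ValueError):
            HaplotypePanel(alleles=np.array([[0, 1], [1, 1]]), freqs=np.array([0.9, 0.9]))


class TestScenarioSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(hypothesis="H0", causal_disease_idx=1),
        dict(hypothesis="H1"),
        dict(hypothesis="H1", causal_disease_idx=1, causal_eqtl_idx=2),
        dict(hypothesis="H2", causal_disease_idx=1, causal_eqtl_idx=1),
        dict(hypothesis="H3", causal_disease_idx=1, causal_eqtl_idx=1),
        dict(hypothesis="H4", causal_disease_idx=1, causal_eqtl_idx=2),
        dict(hypothesis="H4_plus_secondary", causal_disease_idx=1, causal_eqtl_idx=1),
        dict(hypothesis="H5"),
        dict(hypothesis="H0", secondary_eqtl_idx=3),
    ])
    def test_inconsistent_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioSpec(**kwargs)

    def test_valid_h4(self):
        s = ScenarioSpec(hypothesis="H4", causal_disease_idx=3, causal_eqtl_idx=3)
        assert s.causal_disease_idx == s.causal_eqtl_idx


class TestCaseControlGwas:
    def test_determinism_and_counts(self):
        panel = simulate_haplotype_panel(30, 400, rho=0.5, seed=9)
        sc = ScenarioSpec(hypothesis="H0", n_cases=150, n_controls=250, seed=9)
        g1, y1, s1 = simulate_case_control_gwas(panel, sc)
        g2, y2, s2 = simulate_case_control_gwas(panel, sc)
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_array_equal(y1, y2)
        assert [x.p for x in s1] == [x.p for x in s2]
        assert int(y1.sum()) == 150 and int((~y1).sum()) == 250
        assert g1.min() >= 0 and g1.max() <= 2

    def test_null_type_one_error_calibration(self):
        # H0: the fraction of per-SNP score-test p-values below 0.05 should
        # be near 0.05 across replicates
        hits = total = 0
        for seed in range(200):
            panel = simulate_haplotype_panel(50, 400, rho=0.5, seed=seed)
            sc = ScenarioSpec(hypothesis="H0", n_cases=500, n_controls=500, seed=seed)
            _, _, stats = simulate_case_control_gwas(panel, sc)
            hits += sum(1 for s in stats if s.p < 0.05)
            total += len(stats)
        assert 0.03 <= hits / total <= 0.07

    def test_zero_log_or_identical_in_law_to_null(self):
        panel = simulate_haplotype_panel(20, 300, seed=4)
        h0 = ScenarioSpec(hypothesis="H0", n_cases=100, n_controls=100, seed=4)
        h1 = ScenarioSpec(hypothesis="H1", causal_disease_idx=5, log_or=0.0,
                          n_cases=100, n_controls=100, seed=4)
        g0, y0, s0 = simulate_case_control_gwas(panel, h0)
        g1, y1, s1 = simulate_case_control_gwas(panel, h1)
        np.testing.assert_array_equal(g0, g1)
        np.testing.assert_array_equal(y0, y1)
        assert [x.p for x in s0] == [x.p for x in s1]

    def test_causal_snp_attains_min_p(self):
        wins = 0
        for seed in range(50):
            panel = simulate_haplotype_panel(50, 800, rho=0.8, seed=seed)
            sc = ScenarioSpec(hypothesis="H1", causal_disease_idx=25, log_or=0.6,
                              n_cases=2000, n_controls=2000, seed=seed)
            _, _, stats = simulate_case_control_gwas(panel, sc)
            best = min(stats, key=lambda s: s.p)
            wins += best.snp_id == panel.snp_ids[25]
        assert wins >= 45  # >= 90% of 50 replicates

    def test_unattainable_counts_error(self):
        # a strong protective effect makes cases far rarer than the 10%
        # baseline the batch size is tuned for
        panel = simulate_haplotype_panel(5, 50, maf_range=(0.4, 0.5), seed=1)
        sc = ScenarioSpec(hypothesis="H1", causal_disease_idx=0, log_or=-6.0,
                          n_cases=10_000, n_controls=10, seed=1)
        with pytest.raises(RuntimeError):
            simulate_case_control_gwas(panel, sc, max_batches=1)

    def test_case_fraction_recorded(self):
        panel = simulate_haplotype_panel(10, 200, seed=2)
        sc = ScenarioSpec(hypothesis="H0", n_cases=100, n_controls=300, seed=2)
        _, _, stats = simulate_case_control_gwas(panel, sc)
        assert stats[0].case_fraction == pytest.approx(0.25)
        assert stats[0].trait_type == "case-control"


class TestEqtlStudy:
    def test_null_uncorrelated(self):
        panel = simulate_haplotype_panel(30, 800, rho=0.6, seed=11)
        sc = ScenarioSpec(hypothesis="H2", causal_eqtl_idx=10, beta_expr=0.0,
                          n_eqtl1=400, seed=11)
        ds = simulate_eqtl_study(panel, sc, "study1")
        expr = ds.expression["P1"]
        for j in range(ds.Q):
            r = np.corrcoef(ds.dosages[:, j], expr)[0, 1]
            assert abs(r) < 0.15

    def test_slope_recovery(self):
        panel = simulate_haplotype_panel(30, 800, rho=0.6, seed=12)
        sc = ScenarioSpec(hypothesis="H2", causal_eqtl_idx=10, beta_expr=1.0,
                          n_eqtl1=400, seed=12)
        ds = simulate_eqtl_study(panel, sc, "study1")
        stats = {s.snp_id: s for s in fit_cis_eqtl(ds, "P1", standardize=False)}
        causal = stats[panel.snp_ids[10]]
        assert causal.beta == pytest.approx(1.0, abs=0.15)

    def test_determinism_and_study_independence(self):
        panel = simulate_haplotype_panel(10, 200, seed=13)
        sc = ScenarioSpec(hypothesis="H2", causal_eqtl_idx=3, beta_expr=0.5,
                          n_eqtl1=50, n_eqtl2=50, seed=13)
        a = simulate_eqtl_study(panel, sc, "study1")
        b = simulate_eqtl_study(panel, sc, "study1")
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.expression["P1"], b.expression["P1"])
        c = simulate_eqtl_study(panel, sc, "study2")
        assert not np.array_equal(a.dosages, c.dosages)
        assert a.sample_ids != c.sample_ids

    def test_minimum_n(self):
        panel = simulate_haplotype_panel(5, 100, seed=1)
        sc = ScenarioSpec(hypothesis="H0", n_eqtl1=300, n_eqtl2=5, seed=1)
        with pytest.raises(ValueError):
            simulate_eqtl_study(panel, sc, "study2")

    def test_secondary_eqtl_adds_signal(self):
        panel = simulate_haplotype_panel(100, 1000, rho=0.9, seed=14)
        primary = 50
        secondary = pick_tagging_snp(panel, primary, target_r2=0.3)
        r2 = ld_r2(panel.alleles[:, primary].astype(float), panel.alleles[:, secondary].astype(float))
        assert 0.1 < r2 < 0.6  # weak LD with the primary, by construction
        sc = ScenarioSpec(hypothesis="H4_plus_secondary", causal_disease_idx=primary,
                          causal_eqtl_idx=primary, secondary_eqtl_idx=secondary,
                          beta_expr=1.0, log_or=0.4, n_eqtl1=500, seed=14)
        ds = simulate_eqtl_study(panel, sc, "study1")
        stats = {s.snp_id: s for s in fit_cis_eqtl(ds, "P1")}
        t_sec = abs(stats[panel.snp_ids[secondary]].beta) / np.sqrt(stats[panel.snp_ids[secondary]].varbeta)
        assert t_sec > 3  # secondary signal visible


class TestLdR2:
    def test_identical(self):
        v = np.array([0.0, 1.0, 2.0, 1.0])
        assert ld_r2(v, v) == pytest.approx(1.0)

    def test_haplotype_construction(self):
        # AB=40, ab=40, Ab=10, aB=10: D = 0.15, r2 = D^2/(pq pq) = 0.36
        x = np.array([1] * 40 + [0] * 40 + [1] * 10 + [0] * 10, dtype=float)
        y = np.array([1] * 40 + [0] * 40 + [0] * 10 + [1] * 10, dtype=float)
        assert ld_r2(x, y) == pytest.approx(0.36, abs=1e-12)

    def test_orthogonal_patterns(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert ld_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError):
            ld_r2(np.ones(4), np.array([0.0, 1, 2, 1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ld_r2(np.zeros(3), np.zeros(4))


class TestPickers:
    def test_low_ld_pair(self):
        panel = simulate_haplotype_panel(200, 800, rho=0.9, seed=15)
        a, b = pick_low_ld_pair(panel, max_r2=0.05)
        assert a < b
        assert ld_r2(panel.alleles[:, a].astype(float), panel.alleles[:, b].astype(float)) < 0.05

    def test_genotype_frequency_matches_panel(self, small_panel):
        rng_sc = ScenarioSpec(hypothesis="H0", n_eqtl1=2000, seed=8)
        ds = simulate_eqtl_study(small_panel, rng_sc, "study1")
        geno_freq = ds.dosages.mean(axis=0) / 2.0
        np.testing.assert_allclose(geno_freq, small_panel.freqs, atol=0.05)
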