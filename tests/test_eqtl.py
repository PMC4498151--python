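"""Tests for OLS eQTL estimation, response traits and meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocus.eqtl import (
    AlleleMismatchError,
    AssocStat,
    DegenerateTraitError,
    EqtlDataset,
    StrandAmbiguousError,
    fit_cis_eqtl,
    fixed_effects_meta,
    meta_analyse,
    response_expression,
)


def dataset(dosages, expr, probe="P1"):
    dosages = np.asarray(dosages, dtype=float)
    n = dosages.shape[0]
    return EqtlDataset(
        dosages=dosages,
        expression={probe: np.asarray(expr, dtype=float)},
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"rs{j}" for j in range(dosages.shape[1])],
    )


class TestAssocStat:
    def test_requires_one_route(self):
        with pytest.raises(ValueError):
            AssocStat(snp_id="rs1")

    def test_effect_route_needs_positive_varbeta(self):
        with pytest.raises(ValueError):
            AssocStat(snp_id="rs1", beta=0.5, varbeta=0.0)

    def test_summary_route_valid(self):
        s = AssocStat(snp_id="rs1", p=0.5, maf=0.2, n=100)
        assert s.beta is None


class TestFitCisEqtl:
    def test_perfect_fit(self):
        ds = dataset([[0.0], [1.0], [2.0]], [0.0, 1.0, 2.0])
        (s,) = fit_cis_eqtl(ds, "P1", standardize=False)
        assert s.beta == pytest.approx(1.0)
        assert s.varbeta <= 1e-30
        assert s.p <= 1e-100

    def test_closed_form_hand_example(self):
        # x = (0,0,1,1), y = (0,1,1,2): beta = Sxy/Sxx = 1/1 = 1; residuals
        # (-0.5, 0.5, -0.5, 0.5) give SSR = 1, s^2 = SSR/(n-2) = 0.5 and
        # SE = sqrt(s^2/Sxx) = sqrt(0.5)
        ds = dataset([[0.0], [0.0], [1.0], [1.0]], [0.0, 1.0, 1.0, 2.0])
        (s,) = fit_cis_eqtl(ds, "P1", standardize=False)
        assert s.beta == pytest.approx(1.0)
        assert math.sqrt(s.varbeta) == pytest.approx(math.sqrt(0.5))
        assert s.n == 4

    def test_standardization_changes_scale_only(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 50).astype(float)
        y = 0.8 * g + rng.standard_normal(50)
        raw = fit_cis_eqtl(dataset(g[:, None], y), "P1", standardize=False)[0]
        std = fit_cis_eqtl(dataset(g[:, None], y), "P1", standardize=True)[0]
        assert std.p == pytest.approx(raw.p, rel=1e-9)  # t statistic invariant
        assert std.beta == pytest.approx(raw.beta / np.std(y, ddof=1), rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, (30, 2)).astype(float)
        y = g[:, 0] * 0.5 + rng.standard_normal(30)
        base = fit_cis_eqtl(dataset(g, y), "P1")
        perm = rng.permutation(30)
        shuffled = fit_cis_eqtl(dataset(g[perm], y[perm]), "P1")
        for a, b in zip(base, shuffled):
            assert a.beta == pytest.approx(b.beta)
            assert a.varbeta == pytest.approx(b.varbeta)
            assert a.p == pytest.approx(b.p)

    def test_missing_dropped_pairwise(self):
        g = np.array([[0.0, 0.0], [np.nan, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        y = np.array([0.1, 5.0, 1.0, 1.1, 2.0])
        stats = fit_cis_eqtl(dataset(g, y), "P1", standardize=False)
        assert stats[0].n == 4 and stats[1].n == 5

    def test_constant_dosage_skipped(self):
        g = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="constant"):
            stats = fit_cis_eqtl(dataset(g, [0.0, 1.0, 2.0, 1.0]), "P1")
        assert [s.snp_id for s in stats] == ["rs1"]

    def test_too_few_pairs_skipped(self):
        g = np.array([[0.0], [1.0], [np.nan], [np.nan]])
        with pytest.warns(RuntimeWarning, match="complete pairs"):
            stats = fit_cis_eqtl(dataset(g, [0.0, 1.0, 2.0, 3.0]), "P1")
        assert stats == []

    def test_unknown_probe(self):
        with pytest.raises(KeyError):
            fit_cis_eqtl(dataset([[0.0], [1.0], [2.0]], [0, 1, 2]), "nope")

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_t_squared_equals_r_squared_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        g = rng.integers(0, 3, n).astype(float)
        if np.std(g) == 0:
            return
        y = rng.standard_normal(n) + 0.3 * g
        (s,) = fit_cis_eqtl(dataset(g[:, None], y), "P1")
        r = np.corrcoef(g, y)[0, 1]
        t2 = s.beta**2 / s.varbeta
        expected = (n - 2) * r**2 / (1 - r**2)
        assert t2 == pytest.approx(expected, rel=1e-8)


class TestResponseExpression:
    def test_identical_series_degenerate(self):
        base = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(DegenerateTraitError):
            response_expression(base, base.copy())

    def test_constant_shift_degenerate(self):
        base = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(DegenerateTraitError):
            response_expression(base, base + 5.0)

    def test_no_paired_samples(self):
        with pytest.raises(ValueError, match="paired"):
            response_expression(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )

    def test_only_shared_samples_used(self):
        base = pd.Series([1.0, 2.0, 9.0], index=["a", "b", "x"])
        stim = pd.Series([2.0, 1.0, -5.0], index=["a", "b", "y"])
        out = response_expression(base, stim)
        assert set(out.index) == {"a", "b"}
        assert out.to_numpy() == pytest.approx([0.70710678, -0.70710678])

    def test_planted_response_effect_recovered(self):
        rng = np.random.default_rng(21)
        n = 300
        g = rng.integers(0, 3, n).astype(float)
        ids = [f"s{i}" for i in range(n)]
        base = pd.Series(rng.standard_normal(n), index=ids)
        stim = base + 1.0 * g + rng.standard_normal(n)
        trait = response_expression(base, stim)
        ds = EqtlDataset(
            dosages=g[:, None], expression={"resp": trait.loc[ids].to_numpy()},
            sample_ids=ids, snp_ids=["rs0"],
        )
        (s,) = fit_cis_eqtl(ds, "resp", standardize=False)
        # slope on the standardised difference scale
        diff_sd = np.std((stim - base).to_numpy(), ddof=1)
        assert s.beta * diff_sd == pytest.approx(1.0, abs=0.2)


def stat(snp_id="rs1", beta=0.5, varbeta=0.04, n=100, a1="A", a2="G", maf=0.2):
    return AssocStat(snp_id=snp_id, beta=beta, varbeta=varbeta, p=0.5, maf=maf, n=n,
                     allele1=a1, allele2=a2)


class TestFixedEffectsMeta:
    def test_symmetric(self):
        m = fixed_effects_meta(stat(beta=0.5, varbeta=0.04), stat(beta=0.5, varbeta=0.04))
        assert m.beta == pytest.approx(0.5)
        assert m.varbeta == pytest.approx(0.02)
        assert m.n == 200

    def test_hand_computed_weights(self):
        # w = 100 and 33.33: beta = 0.3, varbeta = 0.0075
        m = fixed_effects_meta(stat(beta=0.2, varbeta=0.01), stat(beta=0.6, varbeta=0.03))
        assert m.beta == pytest.approx(0.3)
        assert m.varbeta == pytest.approx(0.0075)

    def test_allele_swap_flips_sign(self):
        s2 = stat(beta=-0.5, a1="G", a2="A")
        m = fixed_effects_meta(stat(beta=0.5), s2)
        assert m.beta == pytest.approx(0.5)

    def test_irreconcilable_alleles(self):
        with pytest.raises(AlleleMismatchError, match="rs1"):
            fixed_effects_meta(stat(), stat(a1="C", a2="T"))

    def test_strand_ambiguous_high_maf_refused(self):
        with pytest.raises(StrandAmbiguousError):
            fixed_effects_meta(stat(a1="A", a2="T", maf=0.45), stat(a1="A", a2="T", maf=0.45))

    def test_strand_ambiguous_low_maf_allowed(self):
        m = fixed_effects_meta(stat(a1="C", a2="G", maf=0.1), stat(a1="C", a2="G", maf=0.1))
        assert m.beta == pytest.approx(0.5)

    def test_different_snp_error(self):
        with pytest.raises(ValueError):
            fixed_effects_meta(stat(), stat(snp_id="rs2"))

    @given(
        st.floats(min_value=-2, max_value=2), st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=-2, max_value=2), st.floats(min_value=1e-4, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_variance_shrinks_and_beta_between(self, b1, v1, b2, v2):
        m = fixed_effects_meta(stat(beta=b1, varbeta=v1), stat(beta=b2, varbeta=v2))
        assert m.varbeta < min(v1, v2)
        assert min(b1, b2) - 1e-12 <= m.beta <= max(b1, b2) + 1e-12


class TestMetaAnalyse:
    def test_pass_through_singletons(self):
        s1 = [stat(snp_id="rs1"), stat(snp_id="rs2")]
        s2 = [stat(snp_id="rs2"), stat(snp_id="rs3")]
        out = {s.snp_id: s for s in meta_analyse(s1, s2)}
        assert set(out) == {"rs1", "rs2", "rs3"}
        assert out["rs1"] is s1[0]
        assert out["rs3"] is s2[1]
        assert out["rs2"].varbeta < s1[1].varbeta

    def test_ambiguous_dropped_with_warning(self):
        s1 = [stat(snp_id="rs1", a1="A", a2="T", maf=0.45)]
        s2 = [stat(snp_id="rs1", a1="A", a2="T", maf=0.45)]
        with pytest.warns(RuntimeWarning, match="strand-ambiguous"):
            out = meta_analyse(s1, s2)
        assert out == []
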