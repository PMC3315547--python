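"""Concordance statistics: scaling, CCA, spline F-tests, category tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omicord import concordance as cc

TIMES7 = (0.25, 1.0, 4.0, 8.0, 13.0, 18.0, 24.0)


def cca_eigen_oracle(X, Y):
    """Brute-force canonical correlations: eigenvalues of the whitened
    cross-covariance product (independent of the SVD implementation)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx, Syy, Sxy = Xc.T @ Xc, Yc.T @ Yc, Xc.T @ Yc
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.sort(np.linalg.eigvals(M).real)[::-1]
    return np.sqrt(np.clip(ev, 0.0, 1.0))


class TestScaleProfile:
    def test_three_point_example(self):
        s = cc.scale_profile([1.0, 2.0, 3.0])
        assert np.allclose(s.values, [-1.0, 0.0, 1.0])

    def test_idempotent_on_scaled_input(self):
        s = cc.scale_profile([0.3, -1.1, 0.8, 0.0, -0.5], TIMES7[:5])
        s2 = cc.scale_profile(s.values, s.times)
        assert np.allclose(s.values, s2.values, atol=1e-12)

    def test_constant_profile_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = cc.scale_profile([5.0, 5.0, 5.0])
        assert s.degenerate

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_scaled_moments(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=rng.integers(3, 12))
        v[0] += 1.0  # guarantee non-constant
        s = cc.scale_profile(v)
        assert abs(s.values.mean()) < 1e-9
        assert abs(s.values.std(ddof=1) - 1.0) < 1e-9


class TestCanonicalCorrelation:
    def test_self_correlation_is_one(self):
        X = np.random.default_rng(0).normal(size=(50, 5))
        assert np.allclose(cc.canonical_correlation(X, X), 1.0)

    def test_invariant_to_column_reversal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 6))
        Y = rng.normal(size=(80, 6))
        a = cc.canonical_correlation(X, Y)
        b = cc.canonical_correlation(X, Y[:, ::-1])
        assert np.allclose(a, b, atol=1e-10)

    def test_invariant_to_affine_recombination(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 5))
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)  # invertible
        shift = rng.normal(size=5)
        a = cc.canonical_correlation(X, Y)
        b = cc.canonical_correlation(X @ A + shift, Y)
        assert np.allclose(a, b, atol=1e-8)

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        Y = rng.normal(size=(200, 6))
        assert np.allclose(
            cc.canonical_correlation(X, Y), cca_eigen_oracle(X, Y), atol=1e-8
        )

    def test_rank_deficient_error_names_columns(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        X[:, 3] = X[:, 0] + X[:, 1]
        Y = rng.normal(size=(30, 4))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            cc.canonical_correlation(X, Y)
        # reduced mode drops the null direction instead
        red = cc.canonical_correlation(X, Y, on_rank_deficient="reduce")
        assert len(red) == 3

    def test_fewer_rows_than_columns_rejected(self):
        X = np.zeros((4, 6))
        with pytest.raises(ValueError, match="rows"):
            cc.canonical_correlation(X, X)

    def test_descending_in_unit_interval(self):
        rng = np.random.default_rng(5)
        r = cc.canonical_correlation(rng.normal(size=(60, 5)), rng.normal(size=(60, 5)))
        assert (np.diff(r) <= 1e-12).all()
        assert ((0 <= r) & (r <= 1)).all()


class TestPermutationCca:
    def test_identical_matrices_minimal_p(self):
        X = np.random.default_rng(6).normal(size=(200, 6))
        res = cc.permutation_test_cca(X, X.copy(), n_perm=99, seed=1)
        assert res.p_values[0] == pytest.approx(1.0 / 100.0)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 4))
        a = cc.permutation_test_cca(X, Y, n_perm=50, seed=3)
        b = cc.permutation_test_cca(X, Y, n_perm=50, seed=3)
        assert np.array_equal(a.perm_correlations, b.perm_correlations)
        assert np.array_equal(a.p_values, b.p_values)

    def test_zero_permutations_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            cc.permutation_test_cca(X, X, n_perm=0)


def _scaled_from(values):
    return cc.scale_profile(values, TIMES7)


class TestSplineFStats:
    def test_basis_shape_and_rank(self):
        B = cc.spline_basis(np.array(TIMES7), df=3)
        assert B.shape == (7, 3)
        X = np.column_stack([np.ones(7), B])
        assert np.linalg.matrix_rank(X) == 4

    def test_identical_profiles_give_zero_f1(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=7)
        s = _scaled_from(v)
        F1, F2 = cc.concordance_f_stats(s, cc.ScaledProfile(s.times, s.values.copy()))
        assert F1 == pytest.approx(0.0, abs=1e-9)

    def test_sign_flip_duality(self):
        rng = np.random.default_rng(9)
        B = cc.spline_basis(np.array(TIMES7))
        shape = B @ rng.normal(0, 0.3, 3)
        s_rna = _scaled_from(shape + rng.normal(0, 0.05, 7))
        s_prot_anti = _scaled_from(-shape + rng.normal(0, 0.05, 7))
        F1, _ = cc.concordance_f_stats(s_rna, s_prot_anti)
        s_rna_neg = cc.ScaledProfile(s_rna.times, -s_rna.values)
        F1_neg, _ = cc.concordance_f_stats(s_rna_neg, s_prot_anti)
        assert F1 > 10 * max(F1_neg, 0.1)
        # duality: negating RNA twice returns the original statistic
        F1_back, _ = cc.concordance_f_stats(
            cc.ScaledProfile(s_rna.times, -s_rna_neg.values), s_prot_anti
        )
        assert F1_back == pytest.approx(F1, rel=1e-9)

    def test_shared_shape_f1_stays_below_null_quantile(self):
        # pairs drawn from one spline shape + noise: F1 should look like a
        # central F(3, 2n-8) draw, i.e. rarely exceed its 0.95 quantile
        rng = np.random.default_rng(10)
        B = cc.spline_basis(np.array(TIMES7))
        n_rep, exceed = 400, 0
        crit = stats.f.ppf(0.95, 3, 2 * 7 - 8)
        for _ in range(n_rep):
            shape = B @ rng.normal(0, 0.3, 3)
            if np.std(shape) < 0.05:
                continue
            a = _scaled_from(shape + rng.normal(0, 0.1, 7))
            b = _scaled_from(shape + rng.normal(0, 0.1, 7))
            F1, _ = cc.concordance_f_stats(a, b)
            exceed += F1 > crit
        assert exceed / n_rep < 0.10

    def test_mismatched_grids_rejected(self):
        a = cc.scale_profile([0.0, 1.0, 2.0, 1.0, 0.0], (1, 2, 3, 4, 5))
        b = cc.scale_profile([0.0, 1.0, 2.0, 1.0, 0.0], (1, 2, 3, 4, 6))
        with pytest.raises(ValueError, match="time grid"):
            cc.concordance_f_stats(a, b)

    def test_too_few_distinct_times_rejected(self):
        a = cc.scale_profile([0.0, 1.0, 2.0, 1.0], (1, 2, 3, 4))
        with pytest.raises(ValueError, match="5 distinct"):
            cc.concordance_f_stats(a, a)


class TestComposite:
    def test_arithmetic(self):
        assert cc.composite_score(2.0, 10.0, a=1.0, b=-1.0) == pytest.approx(8.0)
        assert cc.composite_score(0.0, 0.0) == 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            cc.composite_score(1.0, 1.0, a=0.0, b=-1.0)
        with pytest.raises(ValueError):
            cc.composite_score(1.0, 1.0, a=1.0, b=0.5)

    def test_monotone_in_f2_and_antitone_in_f1(self):
        base = cc.composite_score(2.0, 5.0)
        assert cc.composite_score(2.0, 6.0) > base
        assert cc.composite_score(3.0, 5.0) < base


class TestCategoryCoherence:
    def test_shared_logistic_curve_detected(self):
        rng = np.random.default_rng(11)
        t = np.array(TIMES7)
        curve = -1.0 + 2.0 / (1.0 + np.exp(-0.8 * (t - 8.0)))
        profiles = np.array([curve + rng.normal(0, 0.05, len(t)) for _ in range(6)])
        p = cc.category_coherence(profiles, t)
        assert p < 0.01

    def test_independent_noise_not_flagged_too_often(self):
        rng = np.random.default_rng(12)
        t = np.array(TIMES7)
        hits, reps = 0, 100
        for _ in range(reps):
            profiles = rng.normal(size=(5, len(t)))
            p = cc.category_coherence(profiles, t)
            hits += (not np.isnan(p)) and p < 0.05
        assert hits / reps < 0.12  # ~5% nominal, binomial slack

    def test_two_members_rejected(self):
        with pytest.raises(ValueError, match="3 member"):
            cc.category_coherence(np.zeros((2, 7)), TIMES7)

    def test_marks(self):
        assert cc.coherence_mark(0.005) == "XX"
        assert cc.coherence_mark(0.03) == "X"
        assert cc.coherence_mark(0.5) == ""
        assert cc.coherence_mark(float("nan")) == "NA"


class TestCategoryConcordanceEnrichment:
    def test_exact_rank_sum_example(self):
        # members {10,11,12} vs non-members {1,2,3,4}: the two most extreme
        # of the C(7,3)=35 rank assignments give two-sided p = 2/35
        scores = pd.Series(
            [10.0, 11.0, 12.0, 1.0, 2.0, 3.0, 4.0],
            index=[f"g{i}" for i in range(7)],
        )
        res = cc.category_concordance_enrichment(
            scores, {"cat": {"g0", "g1", "g2"}}
        )
        assert res.loc[0, "wilcoxon_p"] == pytest.approx(2 / 35)
        assert res.loc[0, "direction"] == 1

    def test_all_tied_scores(self):
        scores = pd.Series([1.0] * 6, index=[f"g{i}" for i in range(6)])
        res = cc.category_concordance_enrichment(scores, {"cat": {"g0", "g1"}})
        assert res.loc[0, "wilcoxon_p"] == 1.0
        assert res.loc[0, "direction"] == 0

    def test_single_maximum_member_is_positive(self):
        scores = pd.Series(
            [10.0] + list(range(9)), index=[f"g{i}" for i in range(10)]
        )
        res = cc.category_concordance_enrichment(scores, {"cat": {"g0"}})
        assert res.loc[0, "direction"] == 1

    def test_empty_category_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(ValueError, match="member"):
            cc.category_concordance_enrichment(scores, {"cat": set()})

    def test_label_permutation_calibration(self):
        rng = np.random.default_rng(13)
        hits, reps = 0, 200
        for _ in range(reps):
            scores = pd.Series(rng.normal(size=30),
                               index=[f"g{i}" for i in range(30)])
            members = set(rng.choice(scores.index, size=8, replace=False))
            res = cc.category_concordance_enrichment(scores, {"c": members})
            hits += res.loc[0, "wilcoxon_p"] < 0.05
        assert hits / reps < 0.12
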