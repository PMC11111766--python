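"""Statistical toolbox: t-tests, chi-square, ranks, FDR, correlations, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from netstates import stats as nst


class TestTwoSampleT:
    def test_identical_samples_give_t_zero_p_one(self, rng):
        x = rng.normal(size=10)
        t, df, p = nst.two_sample_t(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)
        assert df == 18

    def test_matches_summary_variant(self, rng):
        x, y = rng.normal(size=20), rng.normal(0.5, 1.3, size=15)
        t1, df1, p1 = nst.two_sample_t(x, y)
        t2, df2, p2 = nst.t_from_summary(x.mean(), x.std(ddof=1), x.size,
                                         y.mean(), y.std(ddof=1), y.size)
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert (df1, p1) == (df2, pytest.approx(p2, abs=1e-12))

    def test_agrees_with_permutation_oracle(self, rng):
        # two-sided p of the pooled t should match the permutation null
        # distribution of the mean difference within Monte-Carlo error
        x, y = rng.normal(0.9, 1, 8), rng.normal(0, 1, 7)
        _, _, p = nst.two_sample_t(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:8].mean() - pooled[8:].mean()) >= obs
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(2 * se, 0.02)

    def test_zero_variance_equal_means(self):
        t, df, p = nst.two_sample_t([1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError):
            nst.two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibration(self, rng):
        """Gaussian null at the study's group sizes rejects ~5% of the time."""
        n_sim = 2000
        x = rng.standard_normal((n_sim, 34))
        y = rng.standard_normal((n_sim, 33))
        t, p = sps.ttest_ind(x, y, axis=1, equal_var=True)
        rate = np.mean(p < 0.05)
        assert 0.04 <= rate <= 0.06


class TestPFromT:
    def test_t_zero_gives_p_one(self):
        assert nst.p_from_t(0.0, 10) == 1.0

    def test_sign_symmetric(self):
        assert nst.p_from_t(2.5, 30) == nst.p_from_t(-2.5, 30)

    @given(st_.floats(0.01, 10), st_.floats(0.02, 5))
    @settings(deadline=None, max_examples=50)
    def test_strictly_decreasing_in_magnitude(self, t, dt):
        assert nst.p_from_t(t + dt, 25) < nst.p_from_t(t, 25)


class TestChiSquare:
    def test_proportional_table_is_null(self):
        chi2, df, p = nst.chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 30, size=4)
            chi2, _, _ = nst.chi_square_2x2([[a, b], [c, d]])
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            nst.chi_square_2x2([[0, 0], [5, 5]])

    def test_fisher_companion(self):
        _, p = nst.fisher_exact_2x2([[8, 2], [1, 5]])
        assert 0 < p < 1


class TestMannWhitney:
    def test_identical_samples_exact_p_one(self):
        u, p = nst.mann_whitney([1.5, 2.5, 3.5], [0.5, 2.0, 4.0])
        assert 0 < p <= 1

    def test_full_separation_enumeration(self):
        # C(6,3) = 20 orderings; both extreme tables -> two-sided p = 2/20
        u, p = nst.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_asymptotic_close_to_exact(self, rng):
        x, y = rng.normal(size=10), rng.normal(0.8, 1, size=10)
        _, p_exact = nst.mann_whitney(x, y)  # 100 <= 400 and continuous
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.01


class TestBHFDR:
    def test_all_equal_stay_equal(self):
        adj = nst.bh_fdr([0.03] * 5)
        assert np.allclose(adj, 0.03)

    def test_step_up_by_hand(self):
        adj = nst.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert nst.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert np.all(nst.bh_fdr(p) >= p - 1e-15)

    def test_decision_rule_equivalence(self, rng):
        """Thresholding adjusted p at alpha equals the classic step-up rule."""
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 30))
            decisions = nst.bh_fdr(p) < 0.05
            # classic BH: reject all p <= p_(k*) with k* the largest k
            # such that p_(k) <= alpha*k/m
            order = np.argsort(p)
            m = p.size
            below = np.flatnonzero(p[order] <= 0.05 * np.arange(1, m + 1) / m)
            classic = np.zeros(m, bool)
            if below.size:
                classic[order[:below[-1] + 1]] = True
            assert np.array_equal(decisions, classic)


class TestPartialPearson:
    def test_no_covariates_equals_plain_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = nst.partial_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_exact_residual_identity(self, rng):
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        y = x + 3 * z
        res = nst.partial_pearson(x, y, z)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_matches_inverse_correlation_formula(self, rng):
        n = 50
        X = rng.normal(size=(n, 4))  # x, y, 2 covariates
        res = nst.partial_pearson(X[:, 0], X[:, 1], X[:, 2:])
        R = np.corrcoef(X, rowvar=False)
        P = np.linalg.inv(R)
        r_oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.r == pytest.approx(r_oracle, abs=1e-10)

    def test_collinear_covariates_error(self, rng):
        z = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            nst.partial_pearson(rng.normal(size=20), rng.normal(size=20),
                                np.column_stack([z, 2 * z]))


class TestSpearman:
    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert nst.spearman(x, y).r == pytest.approx(
            nst.spearman(np.exp(x), y).r, abs=1e-12)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert nst.spearman(x, x[::-1]).r == pytest.approx(-1.0)

    def test_matches_rank_oracle_with_ties(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)  # ties likely
        y = rng.integers(0, 5, size=20).astype(float)
        res = nst.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            nst.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPower:
    def test_minimality_of_returned_n(self):
        spec = nst.PowerSpec(effect_size_d=0.7)
        n = nst.required_sample_size(spec)
        assert nst.power_two_sample_t(0.7, n, n) >= 0.8
        assert nst.power_two_sample_t(0.7, n - 1, n - 1) < 0.8

    def test_large_effect_matches_brute_force(self):
        spec = nst.PowerSpec(effect_size_d=2.0)
        n = nst.required_sample_size(spec)
        brute = next(m for m in range(2, 50)
                     if nst.power_two_sample_t(2.0, m, m) >= 0.8)
        assert n == brute
        assert n < 10

    def test_nonincreasing_in_effect_size(self):
        ns = [nst.required_sample_size(nst.PowerSpec(effect_size_d=d))
              for d in (0.3, 0.5, 0.7, 1.0, 1.5)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            nst.PowerSpec(effect_size_d=-1.0)
        with pytest.raises(ValueError):
            nst.PowerSpec(effect_size_d=0.5, alpha=1.5)
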