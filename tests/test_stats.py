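"""Unit and property tests for the statistical primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from methylong.stats import (
    ContingencyTable2x2,
    bh_fdr,
    bonferroni_threshold,
    chi2_2x2,
    fisher_exact_2x2,
    huber_regress,
    huber_regress_many,
    ivw_meta,
    pca_permutation_select,
    pearson_r,
    prop_test_one_sample,
)


# ---------------------------------------------------------------------------
# Huber robust regression
# ---------------------------------------------------------------------------

class TestHuberRegress:
    def test_noiseless_data_recovers_least_squares_exactly(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        beta_true = np.array([1.5, -2.0])
        y = X @ beta_true
        fit = huber_regress(X, y)
        assert np.allclose(fit.coefficients, beta_true, atol=1e-10)

    def test_large_tuning_limit_equals_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = X @ np.array([0.3, 1.2]) + rng.normal(size=80)
        fit = huber_regress(X, y, tuning=1e6)
        ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.coefficients, ols_coef, atol=1e-8)
        # standard errors reduce to the classic OLS formula too
        resid = y - X @ ols_coef
        sigma2 = resid @ resid / (80 - 2)
        ols_se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        assert np.allclose(fit.standard_errors, ols_se, rtol=1e-6)

    def test_huber_beats_ols_under_gross_outliers(self):
        """Simulation oracle: mean |bias| of the Huber slope under 5%
        gross outliers is below the OLS slope bias (y = 2x + N(0,1))."""
        rng = np.random.default_rng(2)
        n, reps = 500, 1000
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        Y = 2.0 * x + rng.normal(size=(reps, n))
        outliers = rng.random((reps, n)) < 0.05
        Y = Y + np.where(outliers, 50.0, 0.0)
        fit = huber_regress_many(X, Y)
        huber_bias = np.abs(fit.coefficients[:, 1] - 2.0).mean()
        ols = np.linalg.lstsq(X, Y.T, rcond=None)[0]
        ols_bias = np.abs(ols[1] - 2.0).mean()
        assert huber_bias < ols_bias

    def test_matches_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = X @ np.array([0.5, -1.0]) + rng.standard_t(3, size=200)
        ours = huber_regress(X, y)
        rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        assert np.allclose(ours.coefficients, rlm.params, atol=5e-3)

    def test_all_zero_response_gives_null_result(self):
        fit = huber_regress(np.ones((20, 1)), np.zeros(20))
        assert fit.coefficients[0] == 0.0
        assert fit.two_sided_p[0] == 1.0

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(np.linalg.LinAlgError):
            huber_regress(X, np.random.default_rng(0).normal(size=30))

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(60), rng.normal(size=60)])
        Y = rng.normal(size=(5, 60))
        batch = huber_regress_many(X, Y)
        for i in range(5):
            single = huber_regress(X, Y[i])
            assert np.allclose(batch.coefficients[i], single.coefficients)
            assert np.allclose(batch.two_sided_p[i], single.two_sided_p)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.004, 0.5], [0.008, 0.5]),
        ],
    )
    def test_step_up_hand_computations(self, p, expected):
        assert np.allclose(bh_fdr(p), expected)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_capped(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.data())
    def test_monotone_in_p(self, p, data):
        i = data.draw(st.integers(0, len(p) - 1))
        q = bh_fdr(p)
        p2 = list(p)
        p2[i] = min(1.0, p2[i] * 0.5)
        q2 = bh_fdr(p2)
        assert q2[i] <= q[i] + 1e-12

    @pytest.mark.parametrize("level", [0.01, 0.05, 0.2])
    def test_q_thresholding_equals_step_up_procedure(self, level):
        """q < level reproduces the rejections of the step-up rule on p."""
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.uniform(0, 1e-4, 10), rng.uniform(0, 1, 200)])
        q = bh_fdr(p)
        # direct step-up: largest k with p_(k) <= level*k/m, reject all below
        order = np.argsort(p)
        m = len(p)
        below = np.nonzero(p[order] <= level * (np.arange(m) + 1) / m)[0]
        rejected_direct = np.zeros(m, bool)
        if below.size:
            rejected_direct[order[: below.max() + 1]] = True
        assert np.array_equal(q < level, rejected_direct)


class TestBonferroni:
    def test_genome_wide_threshold_rounds_to_printed_value(self):
        thr = bonferroni_threshold(0.05, 439_306)
        assert f"{thr:.2e}" == "1.14e-07"

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_closed_form(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

class TestIvwMeta:
    def test_single_study_identity(self):
        m = ivw_meta([0.5], [0.1])
        assert m.beta == pytest.approx(0.5) and m.se == pytest.approx(0.1)

    def test_equal_studies_shrink_se_by_sqrt2(self):
        m = ivw_meta([0.5, 0.5], [0.1, 0.1])
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.1 / math.sqrt(2))

    def test_closed_form_two_studies(self):
        m = ivw_meta([0.4, 0.8], [0.1, 0.2])
        assert m.beta == pytest.approx(0.48)
        assert m.se == pytest.approx(1 / math.sqrt(125))

    def test_pooled_se_below_every_input_se(self):
        rng = np.random.default_rng(6)
        betas = rng.normal(size=5)
        ses = rng.uniform(0.05, 0.5, size=5)
        m = ivw_meta(betas, ses)
        assert m.se <= ses.min() + 1e-12

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError):
            ivw_meta([0.1, 0.2], [0.1, 0.0])


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def _fisher_oracle(a, b, c, d, sided):
    """Exact enumeration over the hypergeometric support."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)

    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    if sided == "greater":
        return sum(pmf(x) for x in range(a, hi + 1))
    pobs = pmf(a)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= pobs * (1 + 1e-9))


class TestChi2:
    def test_equal_proportions_give_zero(self):
        stat, p = chi2_2x2((10, 90, 20, 180))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, p = chi2_2x2((30, 70, 10, 90))
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(4.07e-4, rel=5e-3)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2((0, 0, 5, 5))

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_equals_squared_two_proportion_z(self, t):
        a, b, c, d = t
        stat, _ = chi2_2x2(t)
        p1, p2 = a / (a + b), c / (c + d)
        pool = (a + c) / (a + b + c + d)
        z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / (a + b) + 1 / (c + d)))
        assert stat == pytest.approx(z**2, rel=1e-9)

    def test_invariant_under_transposition_and_swaps(self):
        t = (7, 13, 21, 9)
        ref = chi2_2x2(t)[0]
        a, b, c, d = t
        for alt in [(a, c, b, d), (c, d, a, b), (b, a, d, c)]:
            assert chi2_2x2(alt)[0] == pytest.approx(ref)


class TestFisher:
    def test_one_sided_tail_enumeration(self):
        assert fisher_exact_2x2((8, 2, 2, 8), "greater") == pytest.approx(
            2126 / 184756
        )

    def test_two_sided_enumeration(self):
        assert fisher_exact_2x2((3, 1, 1, 3), "two") == pytest.approx(34 / 70)

    def test_degenerate_margin_is_one(self):
        assert fisher_exact_2x2((0, 5, 0, 5), "two") == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=80)
    @given(st.tuples(*[st.integers(0, 12)] * 4).filter(lambda t: sum(t) > 0))
    def test_matches_enumeration_oracle(self, t):
        a, b, c, d = t
        for sided in ("two", "greater"):
            assert fisher_exact_2x2(t, sided) == pytest.approx(
                _fisher_oracle(a, b, c, d, sided), rel=1e-9, abs=1e-12
            )

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestPropTest:
    def test_exact_null(self):
        z, p = prop_test_one_sample(50, 100, 0.5)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_formula(self):
        z, p = prop_test_one_sample(60, 100, 0.5)
        assert z == pytest.approx(2.0)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_titanic_z_keeps_precision(self):
        z, p = prop_test_one_sample(2623, 3348, 0.5)
        assert z == pytest.approx(32.8, abs=0.05)
        assert 1e-240 < p < 1e-230

    def test_monotone_in_deviation(self):
        ps = [prop_test_one_sample(50 + k, 100, 0.5)[1] for k in range(0, 40, 5)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prop_test_one_sample(5, 0, 0.5)
        with pytest.raises(ValueError):
            prop_test_one_sample(5, 4, 0.5)


# ---------------------------------------------------------------------------
# permutation PCA selection
# ---------------------------------------------------------------------------

class TestPcaPermutationSelect:
    def test_planted_factor_is_selected(self):
        rng = np.random.default_rng(7)
        n, p = 120, 300
        factor = rng.normal(size=n)
        load = rng.normal(size=p)
        X = np.sqrt(10) * np.outer(factor, load) / np.sqrt(p) + rng.normal(size=(n, p))
        sel = pca_permutation_select(X, n_perm=100, alpha=0.01, max_components=3)
        assert sel.n_selected >= 1
        r = np.corrcoef(sel.scores[:, 0], factor)[0, 1]
        assert abs(r) > 0.9

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 250))
        sel = pca_permutation_select(X, n_perm=100, alpha=0.005, max_components=2)
        assert sel.n_selected == 0

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 40))
        X[:, 3] = 2.5
        sel = pca_permutation_select(X, n_perm=20, alpha=0.01, max_components=2)
        assert sel.variances.size >= 1  # ran despite the constant column

    def test_determinism(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 80))
        a = pca_permutation_select(X, n_perm=50, random_state=1)
        b = pca_permutation_select(X, n_perm=50, random_state=1)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.n_selected == b.n_selected


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_on_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 9.0])
        cx, cy = x - x.mean(), y - y.mean()
        brute = (cx @ cy) / math.sqrt((cx @ cx) * (cy @ cy))
        assert pearson_r(x, y) == pytest.approx(brute, rel=1e-12)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(11)
        assert abs(pearson_r(rng.normal(size=10_000), rng.normal(size=10_000))) < 0.05

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
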