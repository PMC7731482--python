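"""Survival statistics: quartiles, Kaplan-Meier, Cox/LRT, region comparison."""

import numpy as np
import pandas as pd
import pytest
from helpers_oracles import naive_cox_loglik

from shgfb import synthetic
from shgfb.survival import (
    ConvergenceError,
    cox_fit,
    km_estimate,
    lrt,
    q1_vs_rest,
    quartile_assign,
    region_compare,
    sodx_split,
    two_covariate_cox,
)


class TestQuartiles:
    @pytest.mark.parametrize(
        "n, expected",
        [(95, (24, 24, 24, 23)), (92, (23, 23, 23, 23)), (4, (1, 1, 1, 1)), (7, (2, 2, 2, 1))],
    )
    def test_group_sizes_favor_lower_quartiles(self, n, expected):
        rng = np.random.default_rng(0)
        a = quartile_assign(rng.normal(size=n))
        assert a.group_sizes == expected
        assert sum(a.group_sizes) == n

    def test_lowest_values_in_q1(self):
        a = quartile_assign([1.0, 2.0, 3.0, 4.0])
        assert list(a.labels) == ["Q1", "Q2", "Q3", "Q4"]
        assert a.boundaries == (1.0, 2.0, 3.0)

    def test_ties_broken_stably_by_id(self):
        values = [5.0, 5.0, 5.0, 5.0, 1.0, 9.0, 2.0, 8.0]
        ids = list("abcdefgh")
        a = quartile_assign(values, ids)
        b = quartile_assign(values, ids)
        assert list(a.labels) == list(b.labels)
        # the four tied 5.0s are ordered a<b<c<d, so 'a' lands lower than 'd'
        assert a.labels[0] <= a.labels[3]

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            quartile_assign([1.0, 2.0, 3.0])

    def test_q1_vs_rest_partition(self):
        rng = np.random.default_rng(1)
        a = quartile_assign(rng.normal(size=92))
        grouping = q1_vs_rest(a)
        assert grouping.sum() == 23 and (~grouping).sum() == 69


class TestKaplanMeier:
    def test_hand_computed_censored_fixture(self):
        curve = km_estimate([2, 4, 5, 6], [1, 0, 1, 1])
        np.testing.assert_array_equal(curve.event_times, [2, 5, 6])
        np.testing.assert_allclose(curve.survival, [3 / 4, 3 / 8, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [4, 2, 1])
        np.testing.assert_array_equal(curve.censor_times, [4])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 200)
        t[:50] = np.round(t[:50], 1) + 0.01  # introduce ties
        curve = km_estimate(t, np.ones(200, int))
        for ti, si in zip(curve.event_times, curve.survival):
            assert si == pytest.approx((t > ti).mean())

    def test_all_censored_survival_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(10.0) == 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(10, 150))
        d = (rng.random(150) < 0.7).astype(int)
        curve = km_estimate(t, d)
        kmf = KaplanMeierFitter().fit(t, d)
        for ti, si in zip(curve.event_times, curve.survival):
            assert si == pytest.approx(float(kmf.survival_function_at_times(ti).iloc[0]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestCox:
    def test_two_group_hazard_ratio_recovery_and_grid_oracle(self):
        rng = np.random.default_rng(4)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(x))
        fit = cox_fit(t, np.ones(n, int), x)
        assert abs(fit.coefficients[0] - 1.0) < 0.15
        # independent grid search over the naive partial likelihood
        grid = np.linspace(0.5, 1.5, 201)
        lls = [naive_cox_loglik(b, t, np.ones(n, int), x) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.coefficients[0]) <= 0.01
        assert fit.log_partial_likelihood == pytest.approx(
            naive_cox_loglik(fit.coefficients[0], t, np.ones(n, int), x)
        )

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 150
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = np.round(rng.exponential(1 / np.exp(0.5 * x1 - 0.3 * x2)), 1) + 0.05
        d = (rng.random(n) < 0.8).astype(int)
        fit = cox_fit(t, d, np.column_stack([x1, x2]))
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "d": d, "x1": x1, "x2": x2}), "t", "d"
        )
        np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.std_errors, cph.standard_errors_.values, atol=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(cph.log_likelihood_)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        fit = cox_fit(t, np.ones(n, int), x)
        assert abs(fit.coefficients[0]) < 3 * fit.std_errors[0]

    def test_cohort_recovery_negative_interface_effect(self, small_cohort):
        df, truth = small_cohort
        fit = cox_fit(df.mfs_time, df.event, df.ln_fb_interface)
        assert fit.coefficients[0] < 0  # decreasing risk with increasing F/B
        assert abs(fit.coefficients[0] - truth.beta_interface) < 3 * fit.std_errors[0]

    def test_score_test_equals_logrank_for_binary_covariate(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(7)
        n = 80
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.exp(0.7 * x))
        d = (rng.random(n) < 0.9).astype(int)
        from shgfb.survival import _prepare, cox_loglik

        ts, ds, Xs = _prepare(t, d, x.astype(float))
        _, grad, info = cox_loglik(np.zeros(1), ts, ds, Xs)
        score_stat = float(grad @ np.linalg.solve(info, grad))
        lr = logrank_test(t[x == 0], t[x == 1], d[x == 0], d[x == 1])
        assert score_stat == pytest.approx(lr.test_statistic, rel=1e-6)

    def test_perfect_separation_diagnosed(self):
        # covariate orders events before all censoring: monotone likelihood
        t = np.arange(1.0, 21.0)
        d = (t <= 10).astype(int)
        x = -t
        with pytest.raises(ConvergenceError, match="monotone|diverging"):
            cox_fit(t, d, x)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3, 4], [1, 1, 1, 1], [2.0, 2.0, 2.0, 2.0])


class TestLRT:
    def test_identical_models_statistic_zero(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        fit = cox_fit(t, np.ones(n, int), x)
        stat, p = lrt(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile_identity(self):
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        a = cox_fit(t, np.ones(n, int), x)
        b = cox_fit(t, np.ones(n, int), 10.0 * x + 3.0)
        assert a.lrt_statistic == pytest.approx(b.lrt_statistic, rel=1e-6)

    def test_different_data_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        t = rng.exponential(1.0, 50)
        full = cox_fit(t, np.ones(50, int), np.column_stack([x, rng.normal(size=50)]))
        other = cox_fit(t[:40], np.ones(40, int), x[:40])
        with pytest.raises(ValueError, match="nested"):
            lrt(full, other)


class TestTwoCovariateCox:
    def test_planted_covariate_flagged_other_not(self):
        truth = synthetic.CohortTruth(beta_interface=-0.8, beta_bulk=0.0, beta_sodx=0.0)
        df = synthetic.generate_cohort(500, truth, seed=12)
        _, pvals = two_covariate_cox(df.mfs_time, df.event, df.ln_fb_bulk, df.ln_fb_interface)
        assert pvals["ln_fb_interface"] < 0.05
        assert pvals["ln_fb_bulk"] >= 0.05

    def test_duplicated_covariate_diagnosed(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        t = rng.exponential(1.0, 50)
        with pytest.raises((ValueError, ConvergenceError)):
            two_covariate_cox(t, np.ones(50, int), x, x)

    def test_null_joint_lrt_p_roughly_uniform(self):
        ps = []
        for seed in range(80):
            rng = np.random.default_rng(100 + seed)
            n = 80
            x = rng.normal(size=(n, 2))
            t = rng.exponential(1.0, n)
            fit, _ = two_covariate_cox(t, np.ones(n, int), x[:, 0], x[:, 1])
            ps.append(fit.lrt_p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestRegionCompare:
    def test_identical_lists(self):
        stat, p = region_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == 0.0 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            region_compare([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_separated_means_highly_significant(self):
        rng = np.random.default_rng(14)
        bulk = rng.normal(12, 4, 92)
        interface = rng.normal(16, 4, 92)
        stat, p = region_compare(bulk, interface)
        assert p < 1e-4 and stat < 0  # interface > bulk

    def test_unpaired_allows_different_sizes(self):
        rng = np.random.default_rng(15)
        stat, p = region_compare(
            rng.normal(0, 1, 30), rng.normal(0, 1, 40), paired=False
        )
        assert 0 <= p <= 1

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            region_compare([1.0, 2.0], [3.0, 4.0])


class TestSodxSplit:
    def test_boundary_convention(self):
        df = pd.DataFrame({"sodx": [25.9, 26.0, 10.0, 40.0], "x": range(4)})
        low, high = sodx_split(df)
        assert set(low.sodx) == {25.9, 10.0}
        assert set(high.sodx) == {26.0, 40.0}

    def test_missing_sodx_dropped_with_warning(self):
        df = pd.DataFrame({"sodx": [10.0, np.nan, 30.0]})
        with pytest.warns(UserWarning, match="without S-ODX"):
            low, high = sodx_split(df)
        assert len(low) + len(high) == 2

    def test_empty_group_warned(self):
        df = pd.DataFrame({"sodx": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="empty"):
            low, high = sodx_split(df)
        assert high.empty and len(low) == 3
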