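import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petmtv.phantom import CohortConfig, generate_cohort
from petmtv.survival import (CollinearityError, ConvergenceError,
                             compare_cpe_bootstrap, cox_fit, gonen_heller_cpe,
                             km_estimate, log2p1, logrank_test, mtv_agreement,
                             optimal_logrank_cutoff, quartile_groups,
                             stepwise_cox)

from oracles import (cox_grid_argmax, cpe_double_loop, logrank_chi2_two_group)


def _records(time, event, **covs):
    return pd.DataFrame({"time_months": time, "event": event, **covs})


class TestLog2p1:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (7.0, 3.0), (1.0, 1.0)])
    def test_values(self, x, expected):
        assert log2p1(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2p1(-0.1)


class TestCoxFit:
    def test_null_covariate_beta_near_zero_p_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for s in range(60):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(20.0, n)
            df = _records(np.minimum(t, 50.0), (t <= 50.0).astype(int), x=x)
            fit = cox_fit(df, ["x"])
            pvals.append(fit.p_values[0])
            assert abs(fit.beta[0]) < 5 * fit.se[0]
        # p-values roughly uniform under the null
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_tiny_two_group_fixture_matches_grid_search_oracle(self):
        # 4 subjects, no ties, all events
        df = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], x=[1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(df, ["x"])
        oracle = cox_grid_argmax(df["time_months"], df["event"], df["x"])
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_small_fixtures_match_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        df = _records(rng.permutation(np.arange(1.0, n + 1)),
                      np.ones(n, int), x=rng.normal(size=n) * 0.5)
        fit = cox_fit(df, ["x"])
        oracle = cox_grid_argmax(df["time_months"], df["event"], df["x"])
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    def test_parameter_recovery_from_generated_cohort(self):
        cfg = CohortConfig(n_patients=2000, beta={"whole_body": 0.35}, seed=44)
        _, surv = generate_cohort(cfg)
        fit = cox_fit(surv, ["log2_mtv_whole_body"])
        assert abs(fit.beta[0] - 0.35) < 3 * fit.se[0]
        assert fit.hazard_ratios[0] == pytest.approx(math.exp(fit.beta[0]))
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]

    def test_agreement_with_lifelines_efron(self):
        """Independent cross-check of the in-package Newton solver."""
        from lifelines import CoxPHFitter
        cfg = CohortConfig(n_patients=150, seed=9)
        _, surv = generate_cohort(cfg)
        surv["time_months"] = np.ceil(surv["time_months"])  # force ties
        covs = ["log2_mtv_liver", "log2_mtv_bone", "log2_mtv_lymph_node"]
        fit = cox_fit(surv, covs)
        cph = CoxPHFitter().fit(surv[["time_months", "event"] + covs],
                                "time_months", "event")
        np.testing.assert_allclose(fit.beta, cph.params_.to_numpy(), atol=5e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(),
                                   atol=5e-5)

    def test_perfect_separation_raises_naming_covariate(self):
        # the covariate orders risk sets monotonically -> no finite maximum
        df = _records([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6,
                      sep=[5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        with pytest.raises(ConvergenceError, match="sep"):
            cox_fit(df, ["sep"])

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        df = _records(rng.exponential(10, 50), np.ones(50, int), a=x, b=2 * x)
        with pytest.raises((CollinearityError, ConvergenceError)):
            cox_fit(df, ["a", "b"])

    def test_constant_covariate_rejected(self):
        df = _records([1.0, 2.0], [1, 1], c=[1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["c"])

    def test_wald_ci_coverage(self):
        """95% Wald CI for beta covers the truth at the nominal rate."""
        hits, n_cohorts = 0, 200
        for s in range(n_cohorts):
            cfg = CohortConfig(n_patients=200, beta={"whole_body": 0.35},
                               seed=1000 + s)
            _, surv = generate_cohort(cfg)
            fit = cox_fit(surv, ["log2_mtv_whole_body"])
            lo = fit.beta[0] - 1.959963984540054 * fit.se[0]
            hi = fit.beta[0] + 1.959963984540054 * fit.se[0]
            hits += lo <= 0.35 <= hi
        assert 0.92 <= hits / n_cohorts <= 0.98


class TestStepwiseCox:
    def test_signal_covariate_selected_over_noise(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = rng.normal(size=n)
        noise = {f"z{i}": rng.normal(size=n) for i in range(4)}
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        df = _records(np.minimum(t, 60.0), (t <= 60.0).astype(int), x=x, **noise)
        res = stepwise_cox(df, ["x"] + list(noise))
        assert "x" in res.selected

    def test_pure_noise_usually_empty_model(self):
        rng = np.random.default_rng(11)
        empty = 0
        n_sims = 60
        for s in range(n_sims):
            n = 150
            t = rng.exponential(20.0, n)
            df = _records(np.minimum(t, 40.0), (t <= 40.0).astype(int),
                          z1=rng.normal(size=n), z2=rng.normal(size=n))
            res = stepwise_cox(df, ["z1", "z2"])
            empty += not res.selected
        # two independent alpha=0.05 entry chances -> ~90% empty
        assert empty / n_sims > 0.78

    def test_single_weak_candidate_rejected_with_trace(self):
        rng = np.random.default_rng(13)
        n = 200
        t = rng.exponential(20.0, n)
        df = _records(np.minimum(t, 40.0), (t <= 40.0).astype(int),
                      z=rng.normal(size=n))
        res = stepwise_cox(df, ["z", "z"])  # duplicates collapse to one test
        if not res.selected:
            assert res.fit is None
            tested = [e for e in res.trace if e["step"] == "entry-test"]
            assert tested and all(e["p"] >= 0.05 for e in tested)


class TestGonenHellerCPE:
    def test_zero_beta_gives_half(self):
        res = gonen_heller_cpe(np.zeros(10))
        assert res.value == 0.5 and res.degenerate

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        eta = rng.normal(size=rng.integers(3, 21))
        assert gonen_heller_cpe(eta).value == pytest.approx(
            cpe_double_loop(eta), abs=1e-12)

    def test_monotone_in_separation_with_balanced_supremum(self):
        # two equal groups: between-pair fraction n^2/4 over n(n-1)/2
        n = 20
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        values = [gonen_heller_cpe(b * x).value for b in (0.5, 1, 2, 4, 8, 16)]
        assert all(b > a for a, b in zip(values, values[1:]))
        # supremum: between pairs -> 1, within pairs -> 1/2
        n_pairs = n * (n - 1) / 2
        between = (n // 2) ** 2
        sup = (between * 1.0 + (n_pairs - between) * 0.5) / n_pairs
        assert values[-1] < sup
        assert sup - values[-1] < 0.01


class TestCompareCPE:
    def test_model_against_itself_p_one(self):
        cfg = CohortConfig(n_patients=80, seed=2)
        _, surv = generate_cohort(cfg)
        res = compare_cpe_bootstrap(surv, ["log2_mtv_liver"], ["log2_mtv_liver"],
                                    n_replicates=100, seed=3)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_signal_vs_noise_small_p(self):
        rng = np.random.default_rng(19)
        n = 500
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        df = _records(np.minimum(t, 60.0), (t <= 60.0).astype(int), x=x, z=z)
        res = compare_cpe_bootstrap(df, ["x"], ["z"], n_replicates=300, seed=5)
        assert res.cpe_a > res.cpe_b
        assert res.p_value < 0.01


class TestKaplanMeierLogrank:
    def test_uncensored_four_event_hand_computation(self):
        df = _records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        curves = km_estimate(df, ["g"] * 4)
        c = curves["g"]
        np.testing.assert_allclose(c.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(c.times, [1.0, 2.0, 3.0, 4.0])
        assert c.median == 2.0

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(10.0, 100)
        df = _records(t, np.ones(100, int))
        c = km_estimate(df, ["g"] * 100)["g"]
        for time, s in zip(c.times, c.survival):
            assert s == pytest.approx((t > time).mean())

    def test_identical_groups_chi2_zero_p_one(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = _records(t + t, [1] * 10)
        chi2, dof, p = logrank_test(df, ["a"] * 5 + ["b"] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(29)
        df = _records(rng.exponential(10, 60), rng.integers(0, 2, 60))
        g = rng.integers(0, 2, 60)
        chi2_a, _, _ = logrank_test(df, g)
        chi2_b, _, _ = logrank_test(df, 1 - g)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-10)

    def test_matches_hand_rolled_logrank(self):
        rng = np.random.default_rng(31)
        df = _records(rng.exponential(10, 40).round(0) + 1,
                      rng.integers(0, 2, 40))
        g = rng.integers(0, 2, 40)
        chi2, _, _ = logrank_test(df, g)
        assert chi2 == pytest.approx(
            logrank_chi2_two_group(df["time_months"], df["event"], g), rel=1e-9)

    def test_hazard_ratio_two_gives_small_p(self):
        rng = np.random.default_rng(37)
        rejections = 0
        for s in range(30):
            t0 = rng.exponential(20.0, 100)
            t1 = rng.exponential(10.0, 100)
            df = _records(np.r_[t0, t1], np.ones(200, int))
            _, _, p = logrank_test(df, [0] * 100 + [1] * 100)
            rejections += p < 0.05
        assert rejections / 30 > 0.9


class TestOptimalCutoff:
    def test_zero_vs_positive_only_separating_split(self):
        values = [0.0, 0.0, 0.0, 5.0, 6.0, 7.0]
        # high group dies early, low group survives long
        df = _records([50.0, 60.0, 70.0, 2.0, 3.0, 4.0], [1] * 6)
        res = optimal_logrank_cutoff(values, df)
        assert 0.0 < res.cutoff <= 5.0

    @pytest.mark.parametrize("seed", [3, 7])
    def test_scan_matches_brute_force(self, seed):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(seed)
        n = 24
        values = rng.lognormal(1.0, 1.0, n)
        df = _records(rng.exponential(10, n), rng.integers(0, 2, n))
        res = optimal_logrank_cutoff(values, df)
        # brute force every admissible split independently
        best = -np.inf
        distinct = np.unique(values)
        for lo, hi in zip(distinct[:-1], distinct[1:]):
            cut = 0.5 * (lo + hi)
            high = values > cut
            if min(high.sum(), n - high.sum()) < math.ceil(0.1 * n):
                continue
            chi2 = multivariate_logrank_test(
                df["time_months"], high.astype(int), df["event"]).test_statistic
            best = max(best, chi2)
        assert res.chi2 == pytest.approx(best, rel=1e-9)

    def test_invariant_to_monotone_transformation(self):
        rng = np.random.default_rng(41)
        n = 40
        values = rng.lognormal(1.0, 1.0, n)
        df = _records(rng.exponential(10, n), rng.integers(0, 2, n))
        res_raw = optimal_logrank_cutoff(values, df)
        res_log = optimal_logrank_cutoff(np.log(values), df)
        assert res_raw.chi2 == pytest.approx(res_log.chi2, rel=1e-9)
        # the selected partition is the same
        assert np.array_equal(values > res_raw.cutoff,
                              np.log(values) > res_log.cutoff)

    def test_selection_inflation_of_naive_p(self):
        """Scanning for the best split inflates the naive p-value far above
        the nominal level on pure noise."""
        rng = np.random.default_rng(43)
        n_sims, hits = 100, 0
        for s in range(n_sims):
            n = 50
            values = rng.lognormal(1.0, 1.0, n)
            df = _records(rng.exponential(10, n), np.ones(n, int))
            res = optimal_logrank_cutoff(values, df)
            hits += res.p_naive < 0.05
        assert hits / n_sims > 0.15  # far above 5%

    def test_no_admissible_split_is_error(self):
        values = [1.0] * 9 + [2.0]
        df = _records(np.arange(1.0, 11.0), [1] * 10)
        with pytest.raises(ValueError, match="admissible"):
            optimal_logrank_cutoff(values, df, min_arm_frac=0.3)


class TestQuartileGroups:
    def test_eight_values_split_two_each(self):
        labels, collapsed = quartile_groups(np.arange(1.0, 9.0))
        assert not collapsed
        assert list(pd.Series(labels).value_counts().sort_index()) == [2, 2, 2, 2]

    def test_all_equal_collapses(self):
        labels, collapsed = quartile_groups(np.ones(10))
        assert collapsed
        assert np.unique(labels).size == 1

    def test_balanced_groups_for_random_values(self):
        rng = np.random.default_rng(47)
        labels, _ = quartile_groups(rng.normal(size=50))
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1

    def test_boundary_ties_go_to_lower_group(self):
        values = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0])
        labels, _ = quartile_groups(values)
        # 25th percentile is exactly at a tied value; those stay in Q1
        q1 = np.quantile(values, 0.25)
        assert all(l == "Q1" for l, v in zip(labels, values) if v <= q1)


class TestMTVAgreement:
    def test_identity(self):
        a = np.array([1.0, 5.0, 10.0, 20.0])
        rep = mtv_agreement(a, a.copy())
        assert rep["bias"] == 0.0
        assert rep["loa_lower"] == rep["loa_upper"] == 0.0
        assert rep["r_squared_log2"] == pytest.approx(1.0)
        assert rep["wilcoxon_applicable"] is False

    def test_log_scale_shift_keeps_r2_one(self):
        a = np.array([1.0, 3.0, 7.0, 15.0, 31.0, 63.0])
        b = 2.0 * a + 1.0  # log2(b+1) = log2(a+1) + 1
        rep = mtv_agreement(a, b)
        assert rep["r_squared_log2"] == pytest.approx(1.0)
        assert rep["wilcoxon_p"] < 0.05

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(53)
        n = 500
        z = rng.normal(size=n)
        la = z + rng.normal(scale=0.229, size=n)  # corr ~0.95 on log scale
        lb = z + rng.normal(scale=0.229, size=n)
        a = np.exp2(np.abs(la) * 2) - 1
        b = np.exp2(np.abs(lb) * 2) - 1
        rep = mtv_agreement(a, b)
        r = np.corrcoef(log2p1(a), log2p1(b))[0, 1]
        assert rep["r_squared_log2"] == pytest.approx(r ** 2, abs=1e-12)
        assert rep["r_squared_log2"] > 0.7
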