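import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from axsurv.survival import (ConvergenceError, fit_cox, hazard_ratio_ci,
                             kaplan_meier, log_rank, median_follow_up,
                             node_ratio, robust_cluster_variance)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # event at t=5, censoring at t=10: S = 0.5 on [5, 10]
        curve = kaplan_meier([5.0, 10.0], [1, 0])
        assert curve.times.tolist() == [5.0]
        assert curve.survival.tolist() == [0.5]
        assert curve.survival_at([4.9, 5.0, 9.9])[1] == 0.5
        assert curve.survival_at(4.9)[0] == 1.0

    def test_no_events_flat_curve(self):
        curve = kaplan_meier([3, 7, 9], [0, 0, 0])
        assert len(curve.times) == 0
        assert np.all(curve.survival_at([1, 5, 100]) == 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [1, 1])

    def test_matches_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10, 300).round(1)
        curve = kaplan_meier(t, np.ones_like(t))
        grid = np.quantile(t, [0.1, 0.3, 0.5, 0.9])
        emp = np.array([(t > g).mean() for g in grid])
        np.testing.assert_allclose(curve.survival_at(grid), emp, atol=1e-12)

    def test_censoring_processed_after_events_at_tie(self):
        # both subjects counted at risk for the event at t=5
        curve = kaplan_meier([5.0, 5.0], [1, 0])
        assert curve.survival[0] == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.booleans()),
                    min_size=1, max_size=60))
    def test_non_increasing_in_unit_interval(self, data):
        t = [d[0] for d in data]
        e = [int(d[1]) for d in data]
        curve = kaplan_meier(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.r_[[1, 2, 3, 4.0], [1, 2, 3, 4.0]]
        e = np.r_[[1, 0, 1, 0], [1, 0, 1, 0]]
        g = np.r_[np.zeros(4), np.ones(4)]
        stat, p = log_rank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_single_event_time_hand_hypergeometric(self):
        # one event in group 1 at t=1; risk sets n1=2, n0=2, d=1
        t = np.array([1.0, 2.0, 2.0, 2.0])
        e = np.array([1, 0, 0, 0])
        g = np.array([1, 1, 0, 0])
        stat, p = log_rank(t, e, g)
        o_minus_e = 1 - 1 * 2 / 4
        var = 1 * (2 / 4) * (1 - 2 / 4) * (4 - 1) / (4 - 1)
        assert stat == pytest.approx(o_minus_e ** 2 / var)

    def test_p_value_in_unit_interval(self, rng):
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        g = rng.integers(0, 2, 100)
        stat, p = log_rank(t, e, g)
        assert 0.0 <= p <= 1.0

    def test_relabelling_invariance(self, rng):
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        s1, p1 = log_rank(t, e, g)
        s2, p2 = log_rank(t, e, 1 - g)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [1, 1], [0, 0])


class TestFitCox:
    def test_null_covariate(self, rng):
        n = 5000
        x = rng.normal(size=n)
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox(x[:, None], t, e)
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_recovers_true_hr_two_group(self, rng):
        n = 10_000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(np.log(2.0) * x)))
        c = rng.exponential(40, n)
        e = (t <= c).astype(int)
        obs = np.minimum(t, c)
        fit = fit_cox(x[:, None], obs, e, cluster=np.arange(n))
        se = np.sqrt(fit.robust_cov[0, 0])
        assert abs(fit.coef[0] - np.log(2.0)) < 3 * se

    def test_brute_force_partial_likelihood_oracle(self):
        # 6 subjects, single covariate, no ties: grid/scalar maximisation
        # of the independently coded partial likelihood.
        x = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5])
        t = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        e = np.array([1, 0, 1, 1, 0, 1])

        def neg_pl(b):
            ll = 0.0
            for i in range(6):
                if e[i] == 1:
                    risk = t >= t[i]
                    ll += b * x[i] - np.log(np.exp(b * x[risk]).sum())
            return -ll

        res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-10})
        fit = fit_cox(x[:, None], t, e)
        assert abs(fit.coef[0] - res.x) < 1e-4

    def test_matches_lifelines_with_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n),
                          "b": (rng.random(n) < 0.4).astype(float)})
        t = np.ceil(rng.exponential(20, n))
        e = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox(X, t, e, ties="efron")
        df = X.assign(T=t, E=e)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)),
                                   cph.standard_errors_.values, atol=1e-5)

    def test_time_rescaling_invariance(self, rng):
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * x)))
        e = np.ones(n, dtype=int)
        f1 = fit_cox(x[:, None], t, e)
        f2 = fit_cox(x[:, None], t * 7.31, e)
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            fit_cox(np.ones((3, 1)), [1, 2, 3], [0, 0, 0])

    def test_monotone_likelihood_detected(self):
        t = np.arange(1.0, 9.0)
        x = -t  # earliest event always has the largest covariate value
        e = np.ones(8, dtype=int)
        with pytest.raises(ConvergenceError):
            fit_cox(pd.DataFrame({"sep": x}), t, e)

    def test_redundant_column_dropped(self, rng):
        n = 200
        X = pd.DataFrame({"a": rng.normal(size=n)})
        X["b"] = X["a"]
        X["const"] = 1.0
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.6).astype(int)
        fit = fit_cox(X, t, e)
        assert fit.names == ["a"]


class TestRobustClusterVariance:
    def test_singleton_clusters_equal_ordinary_sandwich(self, rng):
        n = 150
        x = rng.normal(size=(n, 2))
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox(x, t, e, cluster=np.arange(n))
        U = fit.score_residuals
        ordinary = fit.cov @ (U.T @ U) @ fit.cov
        np.testing.assert_allclose(fit.robust_cov, ordinary, atol=1e-12)

    def test_hand_computed_four_subject_fixture(self):
        # Independent straight-loop computation of no-ties score residuals
        # and the cluster sandwich for 4 subjects in 2 pairs.
        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 0])
        cluster = np.array([0, 0, 1, 1])
        fit = fit_cox(x[:, None], t, e, cluster=cluster)
        b = fit.coef[0]
        w = np.exp(b * x)
        # score residuals, Breslow form (no ties)
        U = np.zeros(4)
        event_times = t[e == 1]
        for i in range(4):
            for tk in event_times:
                risk = t >= tk
                s0 = w[risk].sum()
                xbar = (w[risk] * x[risk]).sum() / s0
                if t[i] == tk and e[i] == 1:
                    U[i] += x[i] - xbar
                if t[i] >= tk:
                    U[i] -= w[i] / s0 * (x[i] - xbar)
        info = 0.0
        for tk in event_times:
            risk = t >= tk
            s0 = w[risk].sum()
            xbar = (w[risk] * x[risk]).sum() / s0
            info += (w[risk] * (x[risk] - xbar) ** 2).sum() / s0
        Uc = np.array([U[0] + U[1], U[2] + U[3]])
        expected = (Uc ** 2).sum() / info ** 2
        assert fit.robust_cov[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_matches_lifelines_cluster_robust_no_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 200
        X = pd.DataFrame({"a": rng.normal(size=n)})
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        cl = rng.integers(0, 50, n)
        fit = fit_cox(X, t, e, cluster=cl)
        df = X.assign(T=t, E=e, cl=cl)
        cph = lifelines.CoxPHFitter().fit(df, "T", "E", cluster_col="cl",
                                          robust=True)
        np.testing.assert_allclose(np.sqrt(fit.robust_cov[0, 0]),
                                   cph.standard_errors_["a"], rtol=1e-4)

    def test_symmetric_positive_semidefinite(self, rng):
        n = 300
        x = rng.normal(size=(n, 3))
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.6).astype(int)
        fit = fit_cox(x, t, e, cluster=rng.integers(0, 40, n))
        V = fit.robust_cov
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)

    def test_length_mismatch_rejected(self, rng):
        x = rng.normal(size=(10, 1))
        t = rng.exponential(10, 10)
        e = np.ones(10, dtype=int)
        fit = fit_cox(x, t, e)
        with pytest.raises(ValueError):
            robust_cluster_variance(fit, np.arange(5))


class TestHazardRatioCI:
    def test_degenerate_zero_se(self):
        fit = _dummy_fit(coef=0.0, var=0.0)
        hr, lo, hi = hazard_ratio_ci(fit)
        assert (hr[0], lo[0], hi[0]) == (1.0, 1.0, 1.0)

    def test_closed_form(self):
        fit = _dummy_fit(coef=np.log(2.0), var=0.01)
        hr, lo, hi = hazard_ratio_ci(fit)
        z = norm.ppf(0.975)
        assert lo[0] == pytest.approx(np.exp(np.log(2) - z * 0.1))
        assert hi[0] == pytest.approx(np.exp(np.log(2) + z * 0.1))

    def test_ordering(self, rng):
        for _ in range(20):
            fit = _dummy_fit(coef=rng.normal(), var=rng.random())
            hr, lo, hi = hazard_ratio_ci(fit)
            assert lo[0] <= hr[0] <= hi[0]


def _dummy_fit(coef, var):
    from axsurv.survival import SurvivalFit
    return SurvivalFit(names=["x"], coef=np.array([coef]),
                       cov=np.array([[var]]), robust_cov=None, n=10,
                       n_events=5, ties="efron", loglik=0.0, n_iter=1)


class TestNodeRatio:
    @pytest.mark.parametrize("pos,rem,expected", [
        (4, 10, 0.4), (0, 5, 0.0), (7, 7, 1.0),
    ])
    def test_examples(self, pos, rem, expected):
        assert node_ratio(pos, rem) == pytest.approx(expected)

    def test_zero_removed_rejected(self):
        with pytest.raises(ValueError):
            node_ratio(0, 0)


class TestMedianFollowUp:
    def test_observed_median(self):
        assert median_follow_up([1, 2, 3, 4, 100]) == 3.0

    def test_reverse_km(self):
        t = [10.0, 20.0, 30.0, 40.0]
        e = [1, 0, 0, 0]   # censorings at 20, 30, 40
        assert median_follow_up(t, e, method="reverse_km") == 30.0
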