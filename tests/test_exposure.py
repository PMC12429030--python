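import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from axsurv.exposure import (ALND, SLNB, UNKNOWN, ClassifierFit, PriorSpec,
                             build_design, finalize_labels, fit_bayes_logistic,
                             infer_exposure, posterior_prob_alnd, rule_classify)


def oracle_rule(removed, ncat):
    """Independent re-statement of the labelling rules (ALND first)."""
    if removed >= 10:
        return ALND
    if removed >= 7 and ncat >= 1:
        return ALND
    if ncat in (2, 3):
        return ALND
    if 1 <= removed <= 3:
        return SLNB
    if removed <= 4 and ncat == 0:
        return SLNB
    return UNKNOWN


class TestRuleClassify:
    @pytest.mark.parametrize("removed,ncat,expected", [
        (2, 1, SLNB),
        (4, 0, SLNB),
        (12, 0, ALND),
        (7, 1, ALND),
        (5, 0, UNKNOWN),
    ])
    def test_spec_examples(self, removed, ncat, expected):
        label, fired = rule_classify(removed, ncat)
        assert label == expected
        assert (fired == "") == (expected == UNKNOWN)

    def test_exhaustive_oracle_equivalence(self):
        removed = np.repeat(np.arange(1, 83), 4)
        ncat = np.tile(np.arange(4), 82)
        labels, _ = rule_classify(removed, ncat)
        expected = np.array([oracle_rule(r, c) for r, c in zip(removed, ncat)])
        np.testing.assert_array_equal(labels, expected)

    def test_unknown_iff_no_rule_fired(self):
        removed = np.repeat(np.arange(1, 83), 4)
        ncat = np.tile(np.arange(4), 82)
        labels, fired = rule_classify(removed, ncat)
        np.testing.assert_array_equal(labels == UNKNOWN, fired == "")

    def test_invalid_removed_rejected(self):
        with pytest.raises(ValueError):
            rule_classify(0, 0)


class TestBuildDesign:
    def test_centering_at_2010(self):
        rec = pd.DataFrame({"nodes_removed": [3], "year_dx": [2010],
                            "n_category": [0]})
        np.testing.assert_array_equal(build_design(rec),
                                      [[1, 3, 0, 0, 0, 0]])

    def test_indicator_coding(self):
        rec = pd.DataFrame({"nodes_removed": [15], "year_dx": [2000],
                            "n_category": [2]})
        np.testing.assert_array_equal(build_design(rec),
                                      [[1, 15, -10, 0, 1, 0]])

    def test_empty_input(self):
        rec = pd.DataFrame({"nodes_removed": [], "year_dx": [],
                            "n_category": []})
        assert build_design(rec).shape == (0, 6)

    def test_unknown_level_rejected(self):
        rec = pd.DataFrame({"nodes_removed": [3], "year_dx": [2010],
                            "n_category": [5]})
        with pytest.raises(ValueError):
            build_design(rec)


def _synthetic_logistic(n, beta, seed):
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame({
        "nodes_removed": rng.integers(1, 20, n),
        "year_dx": rng.integers(2000, 2021, n),
        "n_category": rng.integers(0, 4, n),
    })
    X = build_design(rec)
    y = rng.random(n) < expit(X @ beta)
    labels = np.where(y, ALND, SLNB)
    return rec, labels


class TestFitBayesLogistic:
    beta_true = np.array([-2.0, 0.4, -0.05, 1.0, 2.0, 2.0])

    def test_parameter_recovery_weak_priors(self):
        rec, labels = _synthetic_logistic(5000, self.beta_true, seed=11)
        weak = PriorSpec(means=np.zeros(6), sds=np.full(6, 10.0))
        fit = fit_bayes_logistic(rec, labels, priors=weak,
                                 method="metropolis", seed=21)
        post_mean = fit.draws.mean(axis=0)
        post_sd = fit.draws.std(axis=0)
        assert np.all(np.abs(post_mean - self.beta_true) < 3 * post_sd)

    def test_laplace_recovery(self):
        rec, labels = _synthetic_logistic(5000, self.beta_true, seed=13)
        weak = PriorSpec(means=np.zeros(6), sds=np.full(6, 10.0))
        fit = fit_bayes_logistic(rec, labels, priors=weak,
                                 method="laplace", seed=22)
        post_sd = fit.draws.std(axis=0)
        assert np.all(np.abs(fit.posterior_mean - self.beta_true) < 3 * post_sd)

    def test_tight_prior_dominates(self):
        rec, labels = _synthetic_logistic(2000, self.beta_true, seed=14)
        priors = PriorSpec(means=np.array([0, 0.6, -0.08, 1.5, 4, 4]),
                           sds=np.array([2.5, 1e-6, 0.04, 1, 1, 1]))
        fit = fit_bayes_logistic(rec, labels, priors=priors,
                                 method="laplace", seed=23)
        assert abs(fit.posterior_mean[1] - 0.6) < 1e-4

    def test_acceptance_rate_in_band(self):
        rec, labels = _synthetic_logistic(2000, self.beta_true, seed=15)
        fit = fit_bayes_logistic(rec, labels, priors=PriorSpec(
            means=np.zeros(6), sds=np.full(6, 10.0)),
            method="metropolis", seed=24)
        assert 0.1 <= fit.acceptance_rate <= 0.6

    def test_single_class_training_rejected(self):
        rec, _ = _synthetic_logistic(100, self.beta_true, seed=16)
        with pytest.raises(ValueError):
            fit_bayes_logistic(rec, [ALND] * 100, seed=1)

    def test_seed_reproducibility(self):
        rec, labels = _synthetic_logistic(1000, self.beta_true, seed=17)
        a = fit_bayes_logistic(rec, labels, method="laplace", seed=9)
        b = fit_bayes_logistic(rec, labels, method="laplace", seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)


def _manual_fit(draws):
    return ClassifierFit(draws=np.asarray(draws, dtype=float),
                         method="manual", n_train=0)


class TestPosteriorProb:
    def test_all_zero_draws_give_half(self):
        fit = _manual_fit(np.zeros((50, 6)))
        rec = pd.DataFrame({"nodes_removed": [4], "year_dx": [2005],
                            "n_category": [1]})
        assert posterior_prob_alnd(fit, rec) == pytest.approx(0.5)

    def test_monotone_in_nodes_removed(self, rng):
        draws = np.zeros((100, 6))
        draws[:, 1] = rng.random(100) + 0.1   # all positive slopes
        fit = _manual_fit(draws)
        rec = pd.DataFrame({"nodes_removed": [9, 3], "year_dx": [2010, 2010],
                            "n_category": [0, 0]})
        p = posterior_prob_alnd(fit, rec)
        assert p[0] > p[1]

    def test_bounds(self, rng):
        fit = _manual_fit(rng.normal(size=(200, 6)) * 3)
        rec = pd.DataFrame({"nodes_removed": rng.integers(1, 80, 50),
                            "year_dx": rng.integers(2000, 2021, 50),
                            "n_category": rng.integers(0, 4, 50)})
        p = posterior_prob_alnd(fit, rec)
        assert np.all((p >= 0) & (p <= 1))


class TestFinalizeLabels:
    rec = pd.DataFrame({"nodes_removed": [5, 5, 12], "year_dx": [2010] * 3,
                        "n_category": [0, 0, 0]})

    def test_unknown_resolved_by_probability(self):
        draws = np.zeros((10, 6))
        draws[:, 0] = 2.0   # p ~ 0.88 for everyone
        final, p = finalize_labels(_manual_fit(draws), self.rec,
                                   [UNKNOWN, ALND, ALND])
        assert final[0] == ALND
        draws[:, 0] = -2.0
        final, _ = finalize_labels(_manual_fit(draws), self.rec,
                                   [UNKNOWN, ALND, ALND])
        assert final[0] == SLNB

    def test_rule_labels_kept(self):
        draws = np.zeros((10, 6))
        draws[:, 0] = -5.0
        final, _ = finalize_labels(_manual_fit(draws), self.rec,
                                   [SLNB, ALND, ALND])
        assert list(final) == [SLNB, ALND, ALND]

    def test_exact_threshold_goes_to_alnd(self):
        final, p = finalize_labels(_manual_fit(np.zeros((10, 6))), self.rec,
                                   [UNKNOWN, UNKNOWN, UNKNOWN])
        assert p[0] == pytest.approx(0.5)
        assert (final == ALND).all()


class TestEndToEnd:
    def test_default_cohort_accuracy(self, default_cohort_10k):
        out, fit = infer_exposure(default_cohort_10k, method="laplace", seed=8)
        assert (out["final_label"] != UNKNOWN).all()
        n23 = out[out["n_category"] >= 2]
        assert (n23["final_label"] == ALND).all()
        acc = (out["final_label"] == out["latent_procedure"]).mean()
        assert acc >= 0.90

    def test_determinism_given_draws(self, default_cohort_10k):
        a, _ = infer_exposure(default_cohort_10k, method="laplace", seed=8)
        b, _ = infer_exposure(default_cohort_10k, method="laplace", seed=8)
        pd.testing.assert_series_equal(a["final_label"], b["final_label"])
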