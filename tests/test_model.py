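"""The three-rate confusion-matrix model and derived metric posteriors."""

import numpy as np
import pytest

from cmbayes import (
    BetaParams,
    ConfusionMatrix,
    ConfusionMatrixModel,
    PointMass,
    UndefinedMetricError,
    acc_direct,
    deceptive_probability,
    exchange_prevalence,
    fit_confusion_model,
    individual_posterior,
    metric_posterior,
    theta_samples,
)
from cmbayes.model import ClassifierPosterior


class TestFit:
    def test_worked_example_margins(self, worked_cm):
        post = fit_confusion_model(worked_cm)
        assert post.tpr == BetaParams(27, 1)
        assert post.tnr == BetaParams(7, 3)
        assert post.phi == BetaParams(27, 9)

    def test_empty_cm_returns_priors(self):
        post = fit_confusion_model(ConfusionMatrix(0, 0, 0, 0))
        assert post.tpr == post.tnr == post.phi == BetaParams(1, 1)

    def test_fixed_prevalence_is_point_mass(self, worked_cm):
        post = fit_confusion_model(worked_cm, prevalence=0.5)
        assert post.phi == PointMass(0.5)
        assert post.tpr == BetaParams(27, 1)  # rates unaffected

    def test_estimator_coercions(self, worked_cm):
        for X in (worked_cm, [26, 0, 2, 6], [[26, 0], [2, 6]],
                  {"TP": 26, "FN": 0, "FP": 2, "TN": 6}):
            m = ConfusionMatrixModel().fit(X)
            assert m.cm_ == worked_cm

    def test_sklearn_params_roundtrip(self):
        m = ConfusionMatrixModel(n_draws=500, random_state=3)
        assert ConfusionMatrixModel(**m.get_params()).get_params() == m.get_params()

    def test_from_predictions(self):
        y_true = [1, 1, 0, 0, 1]
        y_pred = [1, 0, 0, 1, 1]
        m = ConfusionMatrixModel.from_predictions(y_true, y_pred)
        assert m.cm_ == ConfusionMatrix(tp=2, fn=1, fp=1, tn=1)


class TestThetaSamples:
    def test_point_inputs_give_deterministic_rows(self):
        post = ClassifierPosterior(
            phi=PointMass(0.5), tpr=PointMass(1.0), tnr=PointMass(1.0)
        )
        ts = theta_samples(post, n=50, random_state=0)
        np.testing.assert_allclose(ts.draws, np.tile([0.5, 0.0, 0.5, 0.0], (50, 1)))

    def test_all_positive_population(self):
        post = ClassifierPosterior(
            phi=PointMass(1.0), tpr=PointMass(0.8), tnr=BetaParams(2, 2)
        )
        ts = theta_samples(post, n=50, random_state=0)
        np.testing.assert_allclose(ts.draws[:, 0], 0.8)
        np.testing.assert_allclose(ts.draws[:, 1], 0.2)
        np.testing.assert_allclose(ts.draws[:, 2:], 0.0)

    def test_rows_sum_to_one(self, worked_cm):
        ts = ConfusionMatrixModel(random_state=1).fit(worked_cm).sample_theta(5000)
        np.testing.assert_allclose(ts.draws.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(ts.draws >= 0)


class TestMetricPosterior:
    def test_worked_example_tpr(self, worked_cm):
        m = ConfusionMatrixModel(random_state=0).fit(worked_cm)
        mp = m.metric_posterior("tpr")
        assert mp.point == 1.0
        assert round(mp.hpd.lower * 100) == 89
        assert mp.hpd.upper == 1.0

    def test_worked_example_tnr(self, worked_cm):
        m = ConfusionMatrixModel(random_state=0).fit(worked_cm)
        mp = m.metric_posterior("tnr")
        assert mp.point == 0.75
        assert round(mp.hpd.lower * 100) == 43
        assert round(mp.hpd.upper * 100) == 95

    def test_bm_identity_exact(self, worked_cm):
        m = ConfusionMatrixModel(random_state=5).fit(worked_cm)
        ts = m.theta_
        bm = metric_posterior(ts, "bm")
        np.testing.assert_array_equal(bm.draws, ts.tpr + ts.tnr - 1.0)

    def test_acc_on_degenerate_theta(self):
        post = ClassifierPosterior(
            phi=PointMass(0.5), tpr=PointMass(1.0), tnr=PointMass(1.0)
        )
        ts = theta_samples(post, n=200, random_state=0)
        acc = metric_posterior(ts, "acc")
        np.testing.assert_allclose(acc.draws, 1.0)

    def test_unknown_metric_rejected(self, worked_cm):
        m = ConfusionMatrixModel().fit(worked_cm)
        with pytest.raises(KeyError, match="unknown metric"):
            m.metric_posterior("auc")

    def test_draws_within_metric_range(self, worked_cm):
        m = ConfusionMatrixModel(random_state=2, n_draws=5000).fit(worked_cm)
        for name in ("acc", "tpr", "tnr", "ppv", "npv", "f1", "ba"):
            d = m.metric_posterior(name).draws
            assert d.min() >= 0.0 and d.max() <= 1.0
        for name in ("bm", "mcc", "mk"):
            d = m.metric_posterior(name).draws
            assert d.min() >= -1.0 and d.max() <= 1.0

    def test_self_consistent_summary(self, worked_cm):
        mp = ConfusionMatrixModel(random_state=0).fit(worked_cm).metric_posterior("bm")
        assert mp.mu == pytest.approx(mp.hpd.width)


class TestAccRoutes:
    def test_acc_direct_examples(self, worked_cm):
        assert acc_direct(worked_cm) == BetaParams(33, 3)
        assert acc_direct(ConfusionMatrix(0, 0, 0, 0)) == BetaParams(1, 1)
        assert acc_direct(ConfusionMatrix(1, 0, 0, 0)) == BetaParams(2, 1)

    def test_theta_route_mean_with_fixed_phi(self, rng):
        """With prevalence fixed at the empirical fraction and large N, the
        theta-route accuracy mean approaches the observed fraction correct."""
        cm = ConfusionMatrix(tp=40_000, fn=10_000, fp=5_000, tn=45_000)
        m = ConfusionMatrixModel(prevalence=0.5, random_state=0).fit(cm)
        acc = m.metric_posterior("acc")
        assert acc.draws.mean() == pytest.approx((cm.tp + cm.tn) / cm.n, abs=0.002)

    def test_two_routes_agree_up_to_prior_effect(self, rng):
        """The single-binomial and theta-route accuracy posteriors agree up
        to Monte Carlo error plus the O(1/N) difference their priors induce."""
        for _ in range(5):
            n_pos = int(rng.integers(80, 120))
            n_neg = 200 - n_pos
            tp = int(rng.integers(0, n_pos + 1))
            tn = int(rng.integers(0, n_neg + 1))
            cm = ConfusionMatrix(tp=tp, fn=n_pos - tp, fp=n_neg - tn, tn=tn)
            m = ConfusionMatrixModel(random_state=9).fit(cm)
            theta_mean = m.metric_posterior("acc").draws.mean()
            direct_mean = acc_direct(cm).mean
            mc_se = m.metric_posterior("acc").draws.std() / np.sqrt(m.n_draws)
            assert abs(theta_mean - direct_mean) < 2 * mc_se + 2.0 / cm.n


class TestDeceptiveProbability:
    def test_prior_only_is_symmetric(self):
        m = ConfusionMatrixModel(random_state=4).fit(ConfusionMatrix(0, 0, 0, 0))
        r_inf, r_dec = m.deceptive_probability()
        assert r_dec == pytest.approx(0.5, abs=0.02)
        assert r_inf + r_dec == pytest.approx(1.0, abs=0.01)

    def test_perfect_classifier_never_deceptive(self):
        post = ClassifierPosterior(
            phi=BetaParams(2, 2), tpr=PointMass(1.0), tnr=PointMass(1.0)
        )
        ts = theta_samples(post, 1000, random_state=0)
        _, r_dec = deceptive_probability(metric_posterior(ts, "bm"))
        assert r_dec == 0.0

    def test_requires_bm_posterior(self, worked_cm):
        m = ConfusionMatrixModel(random_state=0).fit(worked_cm)
        with pytest.raises(ValueError, match="bookmaker"):
            deceptive_probability(m.metric_posterior("acc"))


class TestPrevalenceExchange:
    def test_ppv_depends_on_prevalence(self, worked_cm):
        m = ConfusionMatrixModel(random_state=6).fit(worked_cm)
        rare = m.exchange_prevalence(0.01)
        assert rare.metric_posterior("ppv").draws.mean() < \
            m.metric_posterior("ppv").draws.mean() - 0.2

    def test_exchange_to_inferred_is_idempotent(self, worked_cm):
        m = ConfusionMatrixModel(random_state=6).fit(worked_cm)
        again = m.exchange_prevalence("inferred")
        assert again.phi_ == m.phi_
        np.testing.assert_array_equal(
            again.metric_posterior("ppv").draws, m.metric_posterior("ppv").draws
        )

    def test_degenerate_prevalence_flags_undefined_metric(self, worked_cm):
        # with phi fixed at 1 there are no true negatives: the Matthews
        # correlation is 0/0 on every draw and the analysis is flagged
        m = ConfusionMatrixModel(random_state=6).fit(worked_cm)
        allpos = m.exchange_prevalence(1.0)
        with pytest.raises(UndefinedMetricError):
            allpos.metric_posterior("mcc")
        # NPV stays defined but collapses to 0 (false negatives remain)
        npv = allpos.metric_posterior("npv")
        np.testing.assert_allclose(npv.draws, 0.0)

    def test_functional_form(self, worked_cm):
        post = fit_confusion_model(worked_cm)
        swapped = exchange_prevalence(post, 0.25)
        assert swapped.phi == PointMass(0.25)
        assert swapped.tpr == post.tpr and swapped.tnr == post.tnr


class TestIndividualPosterior:
    def test_hand_computed_point_rates(self, worked_cm):
        post = ClassifierPosterior(
            phi=PointMass(0.5), tpr=PointMass(0.8), tnr=PointMass(0.8),
        )
        mp = individual_posterior(0.5, post, "positive", n=500, random_state=0)
        np.testing.assert_allclose(mp.draws, 0.8)  # 0.4 / (0.4 + 0.1)

    def test_zero_prior_stays_zero(self, worked_cm):
        post = fit_confusion_model(worked_cm)
        mp = individual_posterior(0.0, post, "positive", n=500, random_state=0)
        np.testing.assert_allclose(mp.draws, 0.0)

    def test_uninformative_test_returns_prior(self):
        post = ClassifierPosterior(
            phi=PointMass(0.5), tpr=PointMass(0.5), tnr=PointMass(0.5),
        )
        mp = individual_posterior(0.5, post, "positive", n=500, random_state=0)
        np.testing.assert_allclose(mp.draws, 0.5)


class TestRecoveryAndScaling:
    def test_parameter_recovery_large_n(self, rng):
        """Posterior means recover generating rates within 1 percentage
        point at N = 100,000."""
        from cmbayes import synthetic_cm

        phi, tpr, tnr = 0.3, 0.85, 0.7
        cm = synthetic_cm(phi, tpr, tnr, 100_000, random_state=rng)
        post = fit_confusion_model(cm)
        assert post.phi.mean == pytest.approx(phi, abs=0.01)
        assert post.tpr.mean == pytest.approx(tpr, abs=0.01)
        assert post.tnr.mean == pytest.approx(tnr, abs=0.01)

    def test_mu_shrinks_like_root_n(self, rng):
        """Median MU of the sensitivity posterior scales like 1/sqrt(N)."""
        from cmbayes import hpd_interval, synthetic_cm

        medians = {}
        for n in (25, 100, 400):
            mus = []
            for _ in range(60):
                cm = synthetic_cm(0.5, 0.8, 0.8, n, random_state=rng)
                post = fit_confusion_model(cm)
                mus.append(hpd_interval(post.tpr).width)
            medians[n] = float(np.median(mus))
        assert medians[25] > medians[100] > medians[400]
        assert medians[25] / medians[400] == pytest.approx(4.0, rel=0.35)


def test_rhat_diagnostic_on_fitted_model(worked_cm):
    m = ConfusionMatrixModel(random_state=0).fit(worked_cm)
    assert set(m.rhat_) == {"phi", "tpr", "tnr"}
    assert m.converged_
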