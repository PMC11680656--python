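"""LCMM likelihood, estimation, posteriors, prediction and diagnostics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from alctraj.lcmm import (
    LcmmFit,
    PosteriorMatrix,
    TrajectoryData,
    TrajectorySpec,
    empirical_bayes_effects,
    fit_multistart,
    fit_single_start,
    loglik_and_grad,
    loglik_components,
    marginal_loglik,
    posterior_probs,
    predict_class_trajectories,
    presentation_order,
    relabel_classes,
    subject_loglik,
    warm_start_from,
    weighted_fit_diagnostic,
    _pack,
)
from alctraj.preprocess import rescale_age
from alctraj.synthetic import default_config, generate_cohort, truth_lcmm_fit


def _design(ages):
    t = rescale_age(np.asarray(ages, dtype=float))
    return np.stack([np.ones_like(t), t, t * t], axis=-1)


def _make_fit(beta, shares, B, sigma):
    beta = np.atleast_2d(beta)
    shares = np.asarray(shares, dtype=float)
    return LcmmFit(
        n_classes=len(shares),
        beta=beta,
        membership_logits=np.log(shares[:-1]) - np.log(shares[-1]),
        re_cholesky=np.linalg.cholesky(np.asarray(B) + 1e-12 * np.eye(3)),
        residual_sd=sigma,
    )


class TestSubjectLoglik:
    def test_one_class_equals_mvn(self):
        ages = np.array([20.0, 30.0, 40.0, 50.0])
        y = np.array([0.5, 1.2, 1.8, 2.0])
        beta = np.array([[1.0, 0.4, -0.1]])
        B = np.diag([0.2, 0.05, 0.01])
        fit = _make_fit(beta, [1.0], B, 0.3)
        X = _design(ages)
        V = X @ B @ X.T + 0.09 * np.eye(4)
        expected = multivariate_normal.logpdf(y, X @ beta[0], V)
        logdens, marg = subject_loglik(y, ages, fit)
        assert marg == pytest.approx(expected, abs=1e-10)
        assert logdens[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_random_effects_reduces_to_univariate_mixture(self):
        ages = np.array([25.0, 45.0])
        y = np.array([1.0, 2.0])
        beta = np.array([[0.5, 0.2, 0.0], [2.0, -0.1, 0.05]])
        shares = np.array([0.3, 0.7])
        sigma = 0.4
        fit = _make_fit(beta, shares, np.zeros((3, 3)), sigma)
        X = _design(ages)
        per_class = np.array(
            [norm.logpdf(y, X @ b, sigma).sum() for b in beta]
        )
        expected = np.logaddexp.reduce(np.log(shares) + per_class)
        logdens, marg = subject_loglik(y, ages, fit)
        assert np.allclose(logdens, per_class, atol=1e-10)
        assert marg == pytest.approx(expected, abs=1e-10)

    def test_matches_monte_carlo_integration(self):
        """The analytic marginal equals MC integration over b ~ N(0, B)."""
        rng = np.random.default_rng(42)
        ages = np.array([20.0, 30.0, 50.0, 57.0])
        beta = np.array([[1.2, 0.5, -0.1], [2.5, 0.1, 0.02]])
        B = np.array([[0.15, 0.02, 0.0], [0.02, 0.03, 0.0], [0.0, 0.0, 0.004]])
        sigma = 0.3
        shares = np.array([0.4, 0.6])
        fit = _make_fit(beta, shares, B, sigma)
        X = _design(ages)
        y = X @ beta[0] + rng.normal(0, 0.4, size=4)

        n_mc = 400_000
        L = np.linalg.cholesky(B + 1e-12 * np.eye(3))
        b = rng.standard_normal((n_mc, 3)) @ L.T
        draws = np.zeros(n_mc)
        for g, share in enumerate(shares):
            mu = X @ beta[g] + b @ X.T
            dens = np.exp(norm.logpdf(y[None, :], mu, sigma).sum(axis=1))
            draws += share * dens
        mc_mean = draws.mean()
        mc_se = draws.std(ddof=1) / np.sqrt(n_mc)

        _, marg = subject_loglik(y, ages, fit)
        assert abs(np.exp(marg) - mc_mean) < 3 * mc_se

    def test_singular_covariance_rejected(self):
        fit = _make_fit(np.zeros((1, 3)), [1.0], np.zeros((3, 3)), 0.0)
        fit.re_cholesky = np.zeros((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            subject_loglik([1.0], [40.0], fit)

    def test_requires_measures(self):
        fit = _make_fit(np.zeros((1, 3)), [1.0], np.eye(3), 0.5)
        with pytest.raises(ValueError):
            subject_loglik([], [], fit)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        cfg = default_config(n_subjects=40, seed=2)
        intakes, _, _ = generate_cohort(cfg)
        data = TrajectoryData.from_frame(intakes)
        theta = _pack(truth_lcmm_fit(cfg))
        _, grad = loglik_and_grad(theta, data, 4)
        num = np.zeros_like(theta)
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            lp = loglik_components(theta + e, data, 4)[0]
            lm = loglik_components(theta - e, data, 4)[0]
            num[i] = (lp - lm) / 2e-6
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-5)


class TestFitting:
    def test_one_class_recovers_ols_limit(self):
        """Nearly noise-free homogeneous data: fixed effects recovered to 1e-3."""
        rng = np.random.default_rng(0)
        beta_true = np.array([1.0, 0.5, -0.1])
        ages = np.tile([20.0, 30.0, 40.0, 50.0, 60.0], (200, 1))
        X = _design(ages[0])
        y = X @ beta_true + rng.normal(0, 1e-3, size=(200, 5))
        import pandas as pd

        frame = pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(200), 5),
                "age_years": ages.ravel(),
                "intake_g_day": np.expm1(y).clip(0).ravel(),
            }
        )
        data = TrajectoryData.from_frame(frame)
        init = _make_fit(np.zeros((1, 3)), [1.0], 0.01 * np.eye(3), 0.1)
        fit = fit_single_start(data, TrajectorySpec(1), init)
        assert fit.converged
        assert np.allclose(fit.beta[0], beta_true, atol=1e-3)

    def test_optimum_at_least_as_good_as_truth(self, fitted_small):
        cfg, data, fit, _, _ = fitted_small
        ll_truth = marginal_loglik(truth_lcmm_fit(cfg), data)
        assert fit.loglik >= ll_truth - 1e-6

    def test_iteration_cap_reported_not_silent(self, small_cohort):
        cfg, intakes, _, _ = small_cohort
        data = TrajectoryData.from_frame(intakes)
        fit = fit_single_start(
            data, TrajectorySpec(4), truth_lcmm_fit(cfg), em_iters=1, max_iter=1
        )
        assert fit.converged is False

    def test_permutation_invariance_of_loglik(self, fitted_small):
        _, data, fit, _, _ = fitted_small
        perm = np.array([2, 0, 3, 1])
        assert marginal_loglik(relabel_classes(fit, perm), data) == pytest.approx(
            fit.loglik, abs=1e-6
        )

    def test_parameter_recovery_from_truth_start(self, fitted_small):
        cfg, data, fit, _, truth = fitted_small
        assert fit.converged
        assert np.allclose(fit.class_shares, cfg.class_shares, atol=0.05)
        assert np.allclose(fit.beta, np.asarray(cfg.class_fixed_effects), atol=0.2)
        # variance ratio: random-intercept variance ~ twice the residual variance
        ratio = fit.re_covariance[0, 0] / fit.residual_sd**2
        true_ratio = cfg.re_covariance[0][0] / cfg.residual_sd**2
        assert ratio == pytest.approx(true_ratio, rel=0.25)


class TestMultistart:
    def test_g1_multistart_is_single_start(self):
        cfg = default_config(n_subjects=150, seed=31)
        intakes, _, _ = generate_cohort(cfg)
        data = TrajectoryData.from_frame(intakes)
        fit = fit_multistart(data, TrajectorySpec(1), n_starts=10, seed=1)
        assert fit.n_starts_used == 1
        assert fit.start_logliks == [fit.loglik]

    def test_replication_stability_two_separated_classes(self):
        cfg = default_config(
            n_subjects=300,
            seed=32,
            class_shares=(0.5, 0.5),
            class_fixed_effects=((0.5, 0.1, 0.0), (2.8, 0.2, -0.05)),
            class_log_hr=(0.2, 0.0),
        )
        intakes, _, _ = generate_cohort(cfg)
        data = TrajectoryData.from_frame(intakes)
        fit = fit_multistart(data, TrajectorySpec(2), n_starts=20, seed=5)
        lls = np.array([ll for ll in fit.start_logliks if np.isfinite(ll)])
        assert np.mean(lls > fit.loglik - 1e-4) >= 0.9

    def test_loglik_nondecreasing_in_G(self):
        cfg = default_config(n_subjects=400, seed=33)
        intakes, _, _ = generate_cohort(cfg)
        data = TrajectoryData.from_frame(intakes)
        lls = []
        prev = None
        base = None
        for G in (1, 2, 3, 4):
            warm = [warm_start_from(prev)] if prev is not None else None
            fit = fit_multistart(
                data, TrajectorySpec(G), n_starts=5, warm_starts=warm, seed=7, base_fit=base
            )
            if G == 1:
                base = fit
            lls.append(fit.loglik)
            prev = fit
        assert all(b >= a - 1e-4 for a, b in zip(lls, lls[1:]))


class TestPosteriors:
    def test_one_class_all_ones(self, small_cohort):
        _, intakes, _, _ = small_cohort
        data = TrajectoryData.from_frame(intakes)
        fit = fit_single_start(
            data, TrajectorySpec(1), _make_fit(np.zeros((1, 3)), [1.0], 0.05 * np.eye(3), 0.5)
        )
        post = posterior_probs(fit, data)
        assert np.allclose(post.probs, 1.0)

    def test_symmetric_classes_give_uniform_rows(self, small_cohort):
        _, intakes, _, _ = small_cohort
        data = TrajectoryData.from_frame(intakes)
        beta = np.tile([1.0, 0.3, -0.05], (3, 1))
        fit = _make_fit(beta, [1 / 3] * 3, 0.1 * np.eye(3), 0.4)
        post = posterior_probs(fit, data)
        assert np.allclose(post.probs, 1 / 3, atol=1e-12)

    def test_hand_computed_bayes_single_measure(self):
        # one measure y at age 35 (t=0), two classes differing in intercept
        y, s, mu1, mu2, p1 = 1.0, np.sqrt(0.25 + 0.04), 0.5, 1.5, 0.4
        num1 = p1 * norm.pdf(y, mu1, s)
        num2 = (1 - p1) * norm.pdf(y, mu2, s)
        expected = num1 / (num1 + num2)
        fit = _make_fit(
            np.array([[mu1, 0, 0], [mu2, 0, 0]]), [p1, 1 - p1], np.diag([0.25, 0, 0]), 0.2
        )
        import pandas as pd

        frame = pd.DataFrame(
            {"subject_id": [1], "age_years": [35.0], "intake_g_day": [np.expm1(y)]}
        )
        post = posterior_probs(fit, TrajectoryData.from_frame(frame))
        assert post.probs[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_rows_sum_to_one_and_modal_rule(self, fitted_small):
        _, _, _, post, _ = fitted_small
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(post.modal_class, post.probs.argmax(axis=1) + 1)

    def test_modal_agreement_with_truth(self, fitted_small):
        _, _, _, post, truth = fitted_small
        agree = np.mean(post.modal_class == truth.class_label)
        assert agree > 0.85

    def test_empirical_bayes_mean_near_zero(self, fitted_small):
        _, data, fit, post, _ = fitted_small
        m_ig, p = empirical_bayes_effects(fit, data)
        b_hat = np.einsum("ng,ngk->nk", p, m_ig)
        scale = np.sqrt(np.diag(fit.re_covariance))
        assert np.all(np.abs(b_hat.mean(axis=0)) < 3 * scale / np.sqrt(data.n_subjects) + 0.02)


class TestPredictionAndDiagnostics:
    def test_intercept_at_age_35(self, fitted_small):
        _, _, fit, _, _ = fitted_small
        pred = predict_class_trajectories(fit, [35.0])
        assert np.allclose(pred["transformed"], fit.beta[:, 0])

    def test_zero_coefficients_zero_curve(self):
        fit = _make_fit(np.zeros((1, 3)), [1.0], np.eye(3), 0.5)
        pred = predict_class_trajectories(fit, np.linspace(20, 65, 10))
        assert np.allclose(pred["intake_g_day"], 0.0)

    def test_guard_warns_outside_range(self, fitted_small):
        _, _, fit, _, _ = fitted_small
        with pytest.warns(UserWarning, match="guard"):
            predict_class_trajectories(fit, [80.0])

    def test_noise_free_diagnostic_observed_equals_predicted(self):
        cfg = default_config(
            n_subjects=80, seed=41, residual_sd=1e-4,
            re_covariance=((0.0,) * 3,) * 3, missing_rate=0.0,
        )
        intakes, _, _ = generate_cohort(cfg)
        data = TrajectoryData.from_frame(intakes)
        init = truth_lcmm_fit(cfg)
        init.residual_sd = 1e-4
        table = weighted_fit_diagnostic(init, data, np.arange(17.5, 72.6, 5.0))
        assert np.allclose(table["observed"], table["predicted"], atol=1e-2)

    def test_calibration_under_true_model(self, fitted_small):
        cfg, data, fit, _, _ = fitted_small
        table = weighted_fit_diagnostic(fit, data, np.arange(17.5, 72.6, 5.0))
        gap = np.abs(table["observed"] - table["predicted"])
        bound = 2 * cfg.residual_sd / np.sqrt(np.maximum(table["weight"], 1.0)) + 0.05
        assert (gap < bound).mean() > 0.9

    def test_presentation_relabel_orders_by_intake(self, fitted_small):
        _, _, fit, _, _ = fitted_small
        order = presentation_order(fit)
        relab = relabel_classes(fit, order)
        t50 = rescale_age(50.0)
        x = np.array([1.0, t50, t50**2])
        values = relab.beta @ x
        assert np.all(np.diff(values) <= 0)
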