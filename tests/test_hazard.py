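"""Baseline hazards, the latent-class PH likelihood and its reductions, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from alctraj.hazard import (
    HazardSpec,
    MSplineBasis,
    build_covariates,
    compare_baselines,
    fit_hazard,
    latent_class_ph_loglik,
    mspline_baseline,
    weibull_hazard,
)
from alctraj.lcmm import PosteriorMatrix
from alctraj.preprocess import assemble_analysis_sets


def _survival_frame(entry, exit_age, event, ids=None):
    n = len(entry)
    return pd.DataFrame(
        {
            "subject_id": ids if ids is not None else np.arange(1, n + 1),
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
        }
    )


class TestWeibull:
    def test_shape_one_is_constant_hazard(self):
        h, H = weibull_hazard(np.array([1.0, 5.0, 20.0]), shape=1.0, scale=4.0)
        assert np.allclose(h, 0.25)
        assert np.allclose(H, np.array([1.0, 5.0, 20.0]) / 4.0)

    def test_cumulative_hazard_one_at_scale(self):
        _, H = weibull_hazard(7.3, shape=2.5, scale=7.3)
        assert H == pytest.approx(1.0)

    def test_numeric_derivative_of_H_matches_h(self):
        grid = np.linspace(1.0, 30.0, 50)
        h, _ = weibull_hazard(grid, shape=3.2, scale=11.0)
        eps = 1e-5
        H_plus = weibull_hazard(grid + eps, 3.2, 11.0)[1]
        H_minus = weibull_hazard(grid - eps, 3.2, 11.0)[1]
        assert np.allclose((H_plus - H_minus) / (2 * eps), h, atol=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            weibull_hazard(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            weibull_hazard(1.0, -1.0, 1.0)


class TestMSpline:
    @pytest.fixture(scope="class")
    def basis(self):
        return MSplineBasis((50.0, 82.0), interior=(62.0, 70.0))

    def test_basis_count(self, basis):
        # cubic with 4 total knots (2 interior): n_interior + degree + 1
        assert basis.n_basis == 6

    def test_each_basis_integrates_to_one(self, basis):
        I_hi = basis.i(np.array([82.0]))[0]
        assert np.allclose(I_hi, 1.0, atol=1e-10)

    def test_zero_coefficients_zero_hazard(self, basis):
        h, H = mspline_baseline(np.linspace(50, 82, 7), basis, np.zeros(6))
        assert np.allclose(h, 0.0) and np.allclose(H, 0.0)

    def test_quadrature_oracle(self, basis):
        rng = np.random.default_rng(4)
        eta = rng.uniform(0.0, 0.3, size=6)
        knots = [50.0, 62.0, 70.0, 82.0]
        for t in (55.0, 64.0, 77.0, 82.0):
            _, H = mspline_baseline(np.array([t]), basis, eta)
            val, _ = quad(
                lambda u: mspline_baseline(np.array([u]), basis, eta)[0][0],
                50.0,
                t,
                points=[k for k in knots if 50.0 < k < t],
                limit=200,
            )
            assert H[0] == pytest.approx(val, abs=1e-6)

    def test_nonnegative_everywhere(self, basis):
        rng = np.random.default_rng(5)
        eta = rng.uniform(0, 1, size=6)
        h, _ = mspline_baseline(np.linspace(50, 82, 500), basis, eta)
        assert (h >= 0).all()

    def test_out_of_range_rejected(self, basis):
        with pytest.raises(ValueError, match="boundary"):
            basis.m(np.array([49.0]))

    def test_negative_coefficient_rejected(self, basis):
        with pytest.raises(ValueError, match="non-negative"):
            mspline_baseline(np.array([60.0]), basis, [-0.1, 0, 0, 0, 0, 0])

    def test_knots_from_data_quantiles(self):
        entry = np.full(100, 50.0)
        exit_age = np.linspace(51, 80, 100)
        event = np.zeros(100, dtype=int)
        event[::2] = 1
        b = MSplineBasis.from_data(entry, exit_age, event, n_knots=5)
        assert b.boundary == (50.0, 80.0)
        assert len(b.interior) == 3
        assert np.all((b.interior > 51) & (b.interior < 80))


class TestLatentClassLoglik:
    def test_one_class_reduces_to_left_truncated_ph(self):
        entry = np.array([50.0, 55.0, 60.0])
        exit_age = np.array([62.0, 70.0, 61.0])
        event = np.array([1, 0, 1])
        surv = _survival_frame(entry, exit_age, event)
        post = PosteriorMatrix.from_probs(np.ones((3, 1)), subject_ids=surv.subject_id.to_numpy())
        spec = HazardSpec(baseline_family="weibull", covariate_set="none")
        shape, scale = 8.0, 95.0
        ll = latent_class_ph_loglik(post, surv, spec, {"xi": [0.0], "shape": shape, "scale": scale})
        h, H_T = weibull_hazard(exit_age, shape, scale)
        _, H_E = weibull_hazard(entry, shape, scale)
        expected = float(np.sum(event * np.log(h) - (H_T - H_E)))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_degenerate_posteriors_equal_modal_loglik(self):
        rng = np.random.default_rng(1)
        n = 40
        entry = rng.uniform(50, 60, n)
        exit_age = entry + rng.uniform(1, 15, n)
        event = rng.integers(0, 2, n)
        surv = _survival_frame(entry, exit_age, event)
        labels = rng.integers(0, 3, n)
        probs = np.eye(3)[labels]
        post = PosteriorMatrix.from_probs(probs, subject_ids=surv.subject_id.to_numpy())
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=3)
        xi = np.array([0.3, 0.6, 0.0])
        params = {"xi": xi, "shape": 6.0, "scale": 90.0}
        ll = latent_class_ph_loglik(post, surv, spec, params)

        h, H_T = weibull_hazard(exit_age, 6.0, 90.0)
        _, H_E = weibull_hazard(entry, 6.0, 90.0)
        risk = np.exp(xi[labels])
        expected = float(
            np.sum(event * (np.log(h) + xi[labels]) - (H_T - H_E) * risk)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_three_subject_exponential_hand_instance(self):
        """Shape-1 Weibull: every term is a pencil-and-paper exponential expression."""
        surv = _survival_frame(
            np.array([2.0, 1.0, 3.0]), np.array([5.0, 4.0, 7.0]), np.array([1, 0, 1])
        )
        probs = np.array([[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
        post = PosteriorMatrix.from_probs(probs, subject_ids=surv.subject_id.to_numpy())
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=2)
        s, xi1 = 10.0, 0.4
        ll = latent_class_ph_loglik(
            post, surv, spec, {"xi": [xi1, 0.0], "shape": 1.0, "scale": s}
        )
        lam = 1.0 / s
        r1 = np.exp(xi1)

        def term(p, E, T, d):
            a = p[0] * (lam * r1) ** d * np.exp(-lam * r1 * (T - E))
            b = p[1] * lam**d * np.exp(-lam * (T - E))
            return np.log(a + b)

        expected = (
            term(probs[0], 2, 5, 1) + term(probs[1], 1, 4, 0) + term(probs[2], 3, 7, 1)
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_equivalence_with_joint_objective(self):
        """Posterior-weighted and joint objectives differ by a hazard-free constant."""
        rng = np.random.default_rng(2)
        n, G = 30, 3
        entry = rng.uniform(50, 60, n)
        exit_age = entry + rng.uniform(1, 15, n)
        event = rng.integers(0, 2, n)
        surv = _survival_frame(entry, exit_age, event)
        a = rng.uniform(0.1, 2.0, size=(n, G))  # pi_g f(Y_i | g)
        probs = a / a.sum(axis=1, keepdims=True)
        post = PosteriorMatrix.from_probs(probs, subject_ids=surv.subject_id.to_numpy())
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=G)

        def weighted(params):
            return latent_class_ph_loglik(post, surv, spec, params)

        def joint(params):
            xi = np.asarray(params["xi"])
            h, H_T = weibull_hazard(exit_age, params["shape"], params["scale"])
            _, H_E = weibull_hazard(entry, params["shape"], params["scale"])
            risk = np.exp(xi)[None, :]
            surv_term = (
                (h[:, None] * risk) ** event[:, None]
                * np.exp(-(H_T - H_E)[:, None] * risk)
            )
            return float(np.log((a * surv_term).sum(axis=1)).sum())

        p1 = {"xi": [0.2, -0.1, 0.0], "shape": 7.0, "scale": 95.0}
        p2 = {"xi": [0.6, 0.3, 0.0], "shape": 5.0, "scale": 105.0}
        assert joint(p1) - joint(p2) == pytest.approx(weighted(p1) - weighted(p2), abs=1e-9)

    def test_entry_at_support_minimum_is_untruncated(self):
        exit_age = np.array([5.0, 8.0, 11.0])
        event = np.array([1, 1, 0])
        eps = 1e-9
        surv = _survival_frame(np.full(3, eps), exit_age, event)
        post = PosteriorMatrix.from_probs(np.ones((3, 1)), subject_ids=surv.subject_id.to_numpy())
        spec = HazardSpec(baseline_family="weibull", covariate_set="none")
        ll = latent_class_ph_loglik(post, surv, spec, {"xi": [0.0], "shape": 2.0, "scale": 9.0})
        h, H_T = weibull_hazard(exit_age, 2.0, 9.0)
        expected = float(np.sum(event * np.log(h) - H_T))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_mismatched_ids_rejected(self):
        surv = _survival_frame(np.array([50.0]), np.array([60.0]), np.array([1]))
        post = PosteriorMatrix.from_probs(np.ones((1, 1)), subject_ids=np.array([999]))
        with pytest.raises(ValueError, match="different subjects"):
            latent_class_ph_loglik(
                post, surv, HazardSpec(covariate_set="none"), {"xi": [0.0], "shape": 1.0, "scale": 1.0}
            )

    def test_entry_after_exit_rejected(self):
        surv = _survival_frame(np.array([65.0]), np.array([60.0]), np.array([1]))
        post = PosteriorMatrix.from_probs(np.ones((1, 1)), subject_ids=surv.subject_id.to_numpy())
        with pytest.raises(ValueError, match="exceed entry"):
            latent_class_ph_loglik(
                post, surv, HazardSpec(covariate_set="none"), {"xi": [0.0], "shape": 1.0, "scale": 1.0}
            )


@pytest.fixture(scope="module")
def survival_fixture(fitted_small):
    cfg, data, fit, post, truth = fitted_small
    from alctraj.synthetic import generate_cohort

    intakes, subjects, _ = generate_cohort(cfg)
    _, surv, _ = assemble_analysis_sets(intakes, subjects)
    sel = np.isin(post.subject_ids, surv["subject_id"].to_numpy())
    pm = PosteriorMatrix.from_probs(post.probs[sel], subject_ids=post.subject_ids[sel])
    return pm, surv


class TestFitHazard:
    def test_reference_class_hr_exactly_one(self, survival_fixture):
        pm, surv = survival_fixture
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4)
        fit = fit_hazard(pm, surv, spec)
        row = fit.hr_table[fit.hr_table["reference"]]
        assert row["HR"].iloc[0] == 1.0
        assert np.isnan(row["ci_low"].iloc[0])
        assert fit.xi[3] == 0.0
        non_ref = fit.hr_table[~fit.hr_table["reference"]]
        assert (non_ref["ci_low"] <= non_ref["HR"]).all()
        assert (non_ref["HR"] <= non_ref["ci_high"]).all()

    def test_model1_covariates_are_quintile_indicators(self, survival_fixture):
        pm, surv = survival_fixture
        W, names = build_covariates(surv, "model1")
        assert W.shape[1] == 4
        assert all(n.startswith("recruitment_quintile") for n in names)

    def test_model2_adds_lifestyle_covariates(self, survival_fixture):
        pm, surv = survival_fixture
        _, names1 = build_covariates(surv, "model1")
        _, names2 = build_covariates(surv, "model2")
        assert len(names2) > len(names1)
        assert any(n.startswith("smoking") for n in names2)

    def test_mspline_and_weibull_compare_by_aic(self, survival_fixture):
        pm, surv = survival_fixture
        fits = []
        for spec in (
            HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4),
            HazardSpec(baseline_family="mspline", n_knots=4, covariate_set="none", reference_class=4),
        ):
            fits.append(fit_hazard(pm, surv, spec))
        chosen, table = compare_baselines(fits)
        assert chosen.aic == table["AIC"].min()
        assert table["chosen"].sum() == 1

    def test_compare_rejects_different_data(self, survival_fixture):
        pm, surv = survival_fixture
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4)
        f1 = fit_hazard(pm, surv, spec)
        surv2 = surv.iloc[:-5]
        pm2 = PosteriorMatrix.from_probs(
            pm.probs[:-5], subject_ids=pm.subject_ids[:-5]
        )
        f2 = fit_hazard(pm2, surv2, spec)
        with pytest.raises(ValueError, match="different data"):
            compare_baselines([f1, f2])

    def test_tie_goes_to_first_listed(self, survival_fixture):
        pm, surv = survival_fixture
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4)
        f1 = fit_hazard(pm, surv, spec)
        chosen, table = compare_baselines([f1, f1])
        assert chosen is f1
        assert table.attrs.get("note", "").startswith("AIC tie")

    def test_class_without_events_gets_infinite_interval(self):
        """A class with no events has an unidentified log-HR (the marginal
        likelihood is monotone toward -inf); the fit reports an unbounded
        Wald interval instead of failing."""
        rng = np.random.default_rng(10)
        n = 60
        entry = rng.uniform(50, 60, n)
        exit_age = entry + rng.uniform(5, 15, n)
        labels = np.repeat([0, 1, 2], n // 3)
        event = np.where(labels == 1, 0, rng.integers(0, 2, n))
        surv = _survival_frame(entry, exit_age, event)
        post = PosteriorMatrix.from_probs(
            np.eye(3)[labels], subject_ids=surv.subject_id.to_numpy()
        )
        spec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=3)
        with pytest.warns(UserWarning, match="unidentified"):
            fit = fit_hazard(post, surv, spec)
        row = fit.hr_table[fit.hr_table["class"] == 2].iloc[0]
        assert row["HR"] < 0.1
        assert not np.isfinite(row["ci_high"]) or row["ci_high"] > 1e3

    def test_fewer_params_wins_on_equal_loglik(self):
        import copy

        from alctraj.hazard import HazardFit

        base = dict(
            spec=HazardSpec(covariate_set="none"),
            n_classes=2,
            xi=np.array([0.1, 0.0]),
            xi_se=np.array([0.1, 0.0]),
            gamma=np.zeros(0),
            gamma_names=[],
            baseline_params={},
            loglik=-100.0,
            cov=np.eye(3),
            hr_table=pd.DataFrame(),
            converged=True,
            data_checksum="x",
            reference_class=2,
        )
        f_small = HazardFit(**base, n_params=3, aic=2 * 3 + 200.0)
        f_big = HazardFit(**base, n_params=5, aic=2 * 5 + 200.0)
        chosen, _ = compare_baselines([f_big, f_small])
        assert chosen is f_small
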