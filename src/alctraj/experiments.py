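"""Simulation experiments verifying the estimation pipeline end to end.

Each experiment generates cohorts from the synthetic model with known truth,
runs the corresponding estimation stage, and summarizes recovery:

* class-number selection on the default 4-class cohort;
* parameter recovery (class shares, high-class log hazard ratio) over
  replicate cohorts;
* confidence-interval coverage of the null hazard ratio when no class
  effect exists;
* Monte-Carlo verification of the mixed-model marginal likelihood.

All randomness is driven by explicit seeds; problem sizes are arguments so
callers can trade precision for runtime.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from alctraj.synthetic import default_config, generate_cohort, truth_lcmm_fit
from alctraj.preprocess import assemble_analysis_sets
from alctraj.lcmm import (
    LcmmFit,
    PosteriorMatrix,
    TrajectoryData,
    TrajectorySpec,
    fit_multistart,
    fit_single_start,
    posterior_probs,
    subject_loglik,
    warm_start_from,
)
from alctraj.model_select import SelectionReport, apply_selection_rules
from alctraj.hazard import HazardSpec, fit_hazard


def selection_recovery(
    n_subjects: int = 3000,
    seed: int = 0,
    classes=(1, 2, 3, 4, 5, 6),
    n_starts: int = 6,
):
    """Fit candidate G on one default cohort and apply the selection rules.

    Returns (SelectionReport, fits dict).  Under the default 4-class
    generator the BIC should fall from G = 1 to 4 and the <5% class-size /
    >=0.75 posterior screens should leave G = 4 as the choice.
    """
    cfg = default_config(n_subjects=n_subjects, seed=seed)
    intakes, _, _ = generate_cohort(cfg)
    data = TrajectoryData.from_frame(intakes)
    report = SelectionReport()
    fits = {}
    base = None
    prev = None
    for G in classes:
        warm = [warm_start_from(prev)] if (prev is not None and prev.n_classes == G - 1) else None
        fit = fit_multistart(
            data, TrajectorySpec(int(G)), n_starts=n_starts, warm_starts=warm,
            seed=seed + 1000 * G, base_fit=base,
        )
        if G == 1:
            base = fit
        fits[int(G)] = fit
        post = posterior_probs(fit, data) if G >= 2 else None
        report.add_candidate(fit, post, data.n_subjects)
        prev = fit
    return apply_selection_rules(report), fits


def recovery_replicates(n_reps: int = 50, n_subjects: int = 1000, seed: int = 0):
    """Replicate-level recovery of class shares and the high-class log-HR.

    Each replicate simulates a default cohort, fits the 4-class LCMM from
    the true parameter values (isolating estimator bias from multistart
    search), computes posteriors, assembles the survival set and fits the
    Weibull latent-class PH model.  Returns per-replicate share estimates
    and high-class log hazard ratios with their Monte-Carlo standard error.
    """
    cfg0 = default_config()
    shares = []
    xi_all = []
    xi_high = []
    for r in range(n_reps):
        cfg = default_config(n_subjects=n_subjects, seed=seed + 7919 * r + 1)
        intakes, subjects, _ = generate_cohort(cfg)
        traj, surv, _ = assemble_analysis_sets(intakes, subjects)
        data = TrajectoryData.from_frame(intakes[intakes["subject_id"].isin(traj["subject_id"])])
        fit = fit_single_start(data, TrajectorySpec(4), truth_lcmm_fit(cfg))
        shares.append(fit.class_shares)
        post = posterior_probs(fit, data)
        sel = np.isin(post.subject_ids, surv["subject_id"].to_numpy())
        pm = PosteriorMatrix.from_probs(post.probs[sel], subject_ids=post.subject_ids[sel])
        hspec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4)
        hfit = fit_hazard(pm, surv, hspec)
        xi_all.append(hfit.xi)
        xi_high.append(hfit.xi[1])  # class 2 is the consistently-high class
    shares = np.asarray(shares)
    xi_all = np.asarray(xi_all)
    xi_high = np.asarray(xi_high)
    return {
        "true_shares": np.asarray(cfg0.class_shares),
        "true_xi": np.asarray(cfg0.class_log_hr),
        "true_xi_high": float(cfg0.class_log_hr[1]),
        "shares": shares,
        "mean_shares": shares.mean(axis=0),
        "xi": xi_all,
        "mean_xi": xi_all.mean(axis=0),
        "xi_high": xi_high,
        "mean_xi_high": float(xi_high.mean()),
        "xi_high_mc_se": float(xi_high.std(ddof=1) / np.sqrt(n_reps)),
    }


def coverage_simulation(n_reps: int = 100, n_subjects: int = 1000, seed: int = 0):
    """Wald-CI coverage of HR = 1 when every class shares the same hazard.

    Stage-1 posteriors come from the true trajectory parameters, so the
    experiment isolates the hazard stage.  Coverage is counted per
    (replicate, non-reference class) confidence interval.
    """
    covered = []
    for r in range(n_reps):
        cfg = default_config(
            n_subjects=n_subjects, seed=seed + 104729 * r + 3,
            class_log_hr=(0.0, 0.0, 0.0, 0.0),
        )
        intakes, subjects, _ = generate_cohort(cfg)
        traj, surv, _ = assemble_analysis_sets(intakes, subjects)
        data = TrajectoryData.from_frame(intakes[intakes["subject_id"].isin(traj["subject_id"])])
        post = posterior_probs(truth_lcmm_fit(cfg), data)
        sel = np.isin(post.subject_ids, surv["subject_id"].to_numpy())
        pm = PosteriorMatrix.from_probs(post.probs[sel], subject_ids=post.subject_ids[sel])
        hspec = HazardSpec(baseline_family="weibull", covariate_set="none", reference_class=4)
        hfit = fit_hazard(pm, surv, hspec)
        hr = hfit.hr_table[~hfit.hr_table["reference"]]
        covered.append(((hr["ci_low"] <= 1.0) & (1.0 <= hr["ci_high"])).to_numpy())
    covered = np.asarray(covered)  # (n_reps, G-1)
    return {
        "covered": covered,
        "coverage_by_class": covered.mean(axis=0),
        "pooled_coverage": float(covered.mean()),
        "n_reps": n_reps,
    }


def mc_loglik_instances(n_instances: int = 5, seed: int = 0, n_draws: int = 200_000):
    """Compare the analytic subject marginal likelihood with MC integration.

    For random small 2-class instances, integrates the conditional density
    over random effects b ~ N(0, B) by simple Monte Carlo and reports the
    analytic value, the MC estimate and its standard error on the density
    scale.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_instances):
        n_meas = int(rng.integers(2, 5))
        ages = np.sort(rng.uniform(20, 65, size=n_meas))
        beta = rng.normal(1.5, 0.8, size=(2, 3)) * np.array([1.0, 0.3, 0.1])
        A = rng.normal(0, 0.3, size=(3, 3)) * np.array([1.0, 0.4, 0.15])
        B = A @ A.T + 1e-4 * np.eye(3)
        sigma = float(rng.uniform(0.2, 0.5))
        share1 = float(rng.uniform(0.2, 0.8))
        shares = np.array([share1, 1 - share1])
        fit = LcmmFit(
            n_classes=2,
            beta=beta,
            membership_logits=np.array([np.log(shares[0] / shares[1])]),
            re_cholesky=np.linalg.cholesky(B),
            residual_sd=sigma,
        )
        t = (ages - 35.0) / 13.0
        X = np.stack([np.ones_like(t), t, t * t], axis=-1)
        y = X @ beta[0] + rng.normal(0, 0.5, size=n_meas)

        L = np.linalg.cholesky(B)
        b = rng.standard_normal((n_draws, 3)) @ L.T
        dens = np.zeros(n_draws)
        for g in range(2):
            mu = X @ beta[g] + b @ X.T
            dens += shares[g] * np.exp(norm.logpdf(y[None, :], mu, sigma).sum(axis=1))
        mc_mean = float(dens.mean())
        mc_se = float(dens.std(ddof=1) / np.sqrt(n_draws))
        _, marg = subject_loglik(y, ages, fit)
        results.append(
            {"analytic": float(np.exp(marg)), "mc": mc_mean, "mc_se": mc_se,
             "abs_z": abs(np.exp(marg) - mc_mean) / mc_se}
        )
    return results
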