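# Methods

## Overview

`alctraj` implements a two-stage analysis of repeated adult alcohol-intake
measures and postmenopausal breast-cancer risk, together with a synthetic
cohort generator that makes every stage verifiable against known ground
truth.

Stage 1 is a latent class mixed model (LCMM): a finite mixture of linear
mixed models in which each latent class g has its own quadratic mean
trajectory on the transformed intake scale and all women share a
random-effect structure,

    y_ij | (class g) = x(t_ij)' beta_g + x(t_ij)' b_i + e_ij,
    x(t) = (1, t, t^2),   t = (age - 35) / 13,
    b_i ~ N(0, B),  e_ij ~ N(0, sigma^2),   P(class g) = pi_g.

Intakes (grams ethanol/day) enter as log(x + 1); age is recentred at 35
years and scaled by 13 years so the quadratic coefficients are O(1).
Marginally, a woman's measure vector is a G-component mixture of
multivariate normals with means X_i beta_g and common covariance
V_i = X_i B X_i' + sigma^2 I, and the log-likelihood sums
log sum_g pi_g phi(y_i; X_i beta_g, V_i) over women.  Women contribute
whatever measures they have (V_i is built per subject); nothing is imputed.

Stage 2 is a parametric proportional-hazards model on the age scale with
delayed entry: a woman of class g has hazard
h_g(t | W) = h0(t) exp(xi_g + gamma' W), and each woman's survival
contribution is marginalized over her stage-1 posterior class
probabilities p_ig,

    l = sum_i log sum_g p_ig [ h_g(T_i)^{d_i} S_g(T_i) / S_g(E_i) ].

Weighting by p_ig rather than the modal class corrects the class hazard
ratios for classification error in the posterior assignment.  Holding the
stage-1 parameters fixed, maximizing this weighted objective is equivalent
to maximizing the joint longitudinal-survival likelihood in the hazard
parameters: the two objectives differ by sum_i log sum_g pi_g f(Y_i|g),
which is free of hazard parameters (asserted numerically in the tests).

## Synthetic cohort generator

The generator draws, per woman: a latent class from `class_shares`; random
effects b ~ N(0, B); transformed intakes at ages 20/30/40/50 and at her
baseline age (uniform on 50-65 years), back-transformed to grams/day as
max(exp(y) - 1, 0) — the exact inverse of the analysis transform, floored
because intakes cannot be negative; class-conditional categorical
covariates; menstrual-history fields driven by a latent age at menopause
~ N(50.5, 3); and a breast-cancer age from a Weibull proportional-hazards
model with class log hazard ratios.  Event ages are sampled by inverse
transform from the survival function *conditional on being event-free at
the baseline age* (the limit of redrawing until the event falls after
entry), so the cohort is cancer-free at entry and both the configured
number of women and the class shares are preserved exactly.  Competing
censoring (death/emigration) is exponential from entry at rate
`censor_rate`; follow-up is administratively capped.  Retrospective
measures are missing completely at random at a small rate (0.5%); the
baseline measure is never missing.  About 7% of women have one adjustment
covariate set missing, to exercise the complete-case exclusion.

Default parameters and their rationale:

| parameter | default | why |
| --- | --- | --- |
| class shares | 0.163, 0.151, 0.506, 0.180 | the reported four-class split of the study population |
| class curves (transformed scale) | (1.50, 0.75, -0.10), (2.90, 0.25, -0.05), (1.85, 0.40, -0.12), (0.60, 0.10, -0.02) | one low-to-moderate class rising from <1 g/day, one consistently high class staying above 10 g/day across ages 20-65, one moderate rising class, one consistently low class below 6 g/day |
| B | diag(0.09, 0.01, 0.0025) | random-intercept variance twice the residual variance (the reported within-class heterogeneity), at a scale where classes remain distinguishable (entropy ~0.85-0.87, all modal-class mean posteriors >= 0.85) and flooring of the back-transform at zero affects only ~5-10% of low-class measures |
| sigma | 0.212 | sigma^2 ~ 0.045 = B[0,0] / 2 |
| Weibull shape, scale | 9, 100 years | ~6.5% of postmenopausal women experience an event over the 17-year horizon, matching the reported case fraction over a 16.5-year median follow-up |
| class log-HRs | log 1.18, log 1.65, log 1.15, 0 | the reported fully adjusted hazard ratios, reference = consistently low |
| censor rate | 0.01 / year | light competing censoring so the median follow-up stays near the administrative horizon |

What the generator does *not* emulate: the joint covariate distribution of
the real cohort (covariates are drawn independently given class, with
contrasts only loosely mirroring the published class profiles); covariate
effects on the hazard (class is the only hazard predictor in truth, so
adjusted fits are correctly specified with zero coefficients); reporting
error and within-class skewness of intake beyond what log-normality
induces; informative censoring.  Passing recovery tests therefore shows
the estimators are correct under the assumed model, not that the model
fits any real cohort.

One deliberate misspecification remains: flooring negative transformed
intakes at zero censors the lower tail of the low-intake classes (a
realistic stand-in for abstainers).  At the default variance scale this
shifts the consistently-low intercept by ~+0.01 on the transformed scale,
well inside estimation noise at the tested sizes.

## Stage-1 estimation

Maximum likelihood via an EM warm-up followed by quasi-Newton refinement:

* E-step/M-step: posterior class probabilities; posterior-weighted
  generalized-least-squares updates for each beta_g; EM updates of B and
  sigma^2 from the conditional moments of the random effects.
* Refinement: L-BFGS-B on the full parameter vector with an analytic
  gradient (verified against finite differences in the tests), using a
  Cholesky factor for B and log(sigma) so constraints hold by
  construction.  Convergence requires relative log-likelihood change below
  1e-8 and a small projected gradient; the iteration cap (500) returns a
  fit flagged `converged=False`, never silently.
* Multistart: random starts perturb the 1-class solution's fixed effects
  per class.  The perturbation scale is the 1-class *between-subject*
  standard deviation (sqrt of the random-effect variances) plus a
  configurable multiple of the asymptotic SEs.  SE-only perturbation
  (a common convention) proved unreliable here: with starts that close to
  symmetric, roughly half of the runs on well-separated two-class data
  collapsed into a merged local optimum in which the random-intercept
  variance absorbs the class separation.  Latent classes live in the
  between-subject distribution, so that spread is the appropriate
  exploration scale; with it, all starts on the same data reached the
  global optimum.  For G >= 5 (and optionally any G), a warm start derived
  from the (G-1)-class fit splits its largest class.  Ties across equally
  good starts resolve to the lowest start index.
* Labels: estimation is label-agnostic; an explicit utility reorders
  classes by natural-scale mean intake for presentation only, and the
  consistently-low class (last after reordering) is the hazard reference.

The membership model is intercept-only (no covariates predict class), and
B is common across classes.  Only the class means are perturbed across
starts; B and sigma start at their 1-class estimates.

## Class-number selection

For candidates G = 1..6: BIC = -2 loglik + p log N with N = number of
women (the mixture-over-subjects convention); relative entropy
1 - sum_i sum_g(-p_ig log p_ig) / (N log G); ICL = BIC
- 2 sum_i log p_i,modal(i) (so ICL >= BIC, equality only under certain
classification).  These are the standard definitions of entropy and ICL,
adopted because the analysis they mirror reports only the criterion names.
Hard screens: smallest class share >= 5% and modal-class mean posterior
>= 0.75 in every class; among survivors the lowest BIC wins (ICL is always
reported; when the two disagree, BIC decides — a deterministic rule is
required and both values appear in the trace).

## Stage-2 estimation

The baseline hazard is Weibull (shape, scale) or a cubic M-spline
h0(t) = sum_k eta_k M_k(t) with eta_k >= 0; the cumulative hazard uses the
corresponding I-spline basis, exact because each M-spline basis function
integrates to one over its support.  Interior knots sit at equally spaced
quantiles of the observed event ages; boundary knots at the minimum entry
and maximum exit age; `n_knots` counts total knots, so cubic bases number
n_knots + 2.  Both 5- and 4-knot splines are fitted and compared with the
Weibull by AIC = 2p - 2 loglik.

Optimization is BFGS on (xi_free, gamma, log baseline parameters), with a
Nelder-Mead polish if the line search stalls.  The covariance of the
estimates is the inverse observed information (numerical Hessian at the
optimum), conditioning on the stage-1 estimates; hazard-ratio CIs are Wald
on the log scale, and spline-coefficient SEs use the delta method.  When a
spline coefficient is pinned at its zero boundary the information matrix
is singular in that direction; the covariance then falls back to a
pseudo-inverse with a warning (the hazard-ratio block is unaffected).  A
flat direction involving the hazard-ratio or covariate block instead
raises an error naming the collinear columns.  Covariate sets: "model1"
= recruitment quintile as four indicators (age is the timescale, never a
covariate); "model2" adds the eight lifestyle/reproductive categoricals as
reference-coded indicators; "none" (no covariates) serves the simulation
experiments, whose generator attaches no covariate effects to the hazard.

First-stage uncertainty is not propagated into the reported SEs (the
two-stage convention of conditioning on stage 1); this understates
uncertainty when class separation is poor.

## Preprocessing conventions

* Beverage frequencies convert to grams ethanol/day with the constants
  8.9 / 12.2 / 17.5 g per bottle (light/regular/strong beer), 12.5 g per
  glass of wine, 9.3 g per fortified-wine drink, 9.9 g per spirits drink.
  The 12 reported frequency categories map to servings/day via category
  midpoints (months = 30 days), with the open ">= 8/day" category mapped
  to 8; the mapping lives in one documented table constant.
* Menopausal status follows a fixed rule cascade (post for >= 12 months
  amenorrhoea or bilateral ovariectomy; age bands for missing
  history/hysterectomy/hormone use, with ">= 55 -> post" taking precedence
  over "46-55 -> peri" at exactly 55; peri for oligomenorrhoea or recent
  cessation; otherwise pre), and perimenopausal recodes to postmenopausal
  for analysis.
* The energy-ratio trim drops values strictly beyond the 1st/99th
  empirical percentiles (linear interpolation); ties at the cut are kept,
  so a constant vector loses no one.
* The survival set is complete-case on the eight fully-adjusted-model
  covariates; the trajectory set is not restricted by menopausal status or
  covariate completeness.

## Problem sizes and numerical tolerances

The bundled experiments run at desk scale: selection on one n = 3,000
cohort with 6 random starts plus a warm start per G; recovery over 50
replicates of n = 1,000 (fits started at the true values, isolating
estimator bias from multistart search); coverage over 100 null replicates
of n = 1,000 with stage-1 posteriors computed at the true trajectory
parameters (isolating the hazard stage).  Posterior rows sum to 1 within
1e-10; likelihood reductions hold to 1e-10; Monte-Carlo likelihood checks
use 2e5-4e5 draws and a 3-standard-error band.

## Known limitations

* Class-specific random-effect covariances, covariates in the membership
  model, and joint longitudinal-survival estimation are out of scope.
* Wald intervals only; no profile likelihood or bootstrap CIs (a
  parametric bootstrap for two-stage uncertainty is a natural extension).
* The plug-in back-transform exp(curve) - 1 reports the median-type curve
  of the class mean, not the expectation of intake on the natural scale.
* BIC at these sample sizes can keep improving past the true G when
  classes overlap; the class-size and posterior screens are what anchor
  the selection in the bundled experiments, mirroring how the selection
  rules are meant to work in practice.
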