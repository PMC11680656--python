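# alctraj

Latent-class trajectories of adult alcohol consumption and postmenopausal
breast-cancer risk, with a classification-error-corrected hazard model and
a fully synthetic, ground-truth-known cohort generator.

The package is for biostatisticians and epidemiologists who analyse
repeated exposure measures in cohort studies: it identifies subgroups of
women with similar drinking trajectories across adulthood from sparse
repeated intake reports, then asks whether trajectory membership predicts
breast-cancer incidence — without pretending the latent classes are
observed.

## The model

**Stage 1 — latent class mixed model (LCMM).** Woman *i* has up to five
ethanol-intake measures (grams/day, reported retrospectively at ages
20/30/40/50 plus a baseline food-frequency questionnaire at age 50–65).
On the transformed scale *y* = log(*x* + 1) with rescaled age
*t* = (age − 35)/13,

  y_ij | (class g) = x(t_ij)ᵀβ_g + x(t_ij)ᵀb_i + ε_ij,  x(t) = (1, t, t²),

with class probabilities π_g (intercept-only multinomial), shared random
effects b_i ~ N(0, B) and residual ε ~ N(0, σ²). Estimation is multistart
maximum likelihood; the number of classes G is chosen among 1..6 by BIC,
entropy and ICL subject to two screens (no class below 5% of women; mean
posterior probability ≥ 0.75 in every modal class).

**Stage 2 — proportional hazards across classes with delayed entry.**
With age as the timescale, class-g hazard h_g(t|W) = h₀(t)·exp(ξ_g + γᵀW)
(reference class: consistently low consumption, ξ ≡ 0). Each woman's
left-truncated survival contribution is marginalized over her stage-1
posterior class probabilities p_ig, which corrects the hazard ratios
exp(ξ_g) for classification error in the modal assignment. The baseline
hazard is Weibull or a cubic M-spline (5 or 4 knots), chosen by AIC.
Model 1 adjusts for recruitment quintile; Model 2 adds eight
lifestyle/reproductive covariates.

Because the motivating cohort is not public, the package ships a generator
(`alctraj.synthetic`) that simulates cohorts with exactly this structure —
four classes with shares (16.3%, 15.1%, 50.6%, 18.0%), class hazard ratios
(1.18, 1.65, 1.15, 1), Weibull baseline sized to ~6.5% incident cases over
a 17-year follow-up — so every estimator is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a
simulated cohort of 3,000 women and write tables under `results/run/`:

```bash
python analysis/01_simulate_cohort.py     # cohort + ground truth
python analysis/02_assemble_cohort.py     # exclusion flow
python analysis/03_fit_trajectories.py    # LCMMs, G = 1..6
python analysis/04_select_classes.py      # BIC/entropy/ICL + screens
python analysis/05_fit_hazard.py          # error-corrected PH, Models 1-2
python analysis/06_report.py              # markdown summary
```

The exclusion flow prints an ordered accounting whose identity
(initial − Σ excluded = final) is checked at every step:

```
input women: 3000
  energy_ratio_1pct_trim: excluded 60, remaining 2940
  premenopausal_at_baseline: excluded 240, remaining 2700
  missing_model2_covariates: excluded 194, remaining 2506
```

Class-number selection on this cohort (seed 20250922) retains G = 4: BIC
falls monotonically from G = 1 to 4, and the 5- and 6-class candidates are
discarded because a modal class drops below the 0.75 mean-posterior
screen:

```
G  loglik        BIC          ICL          entropy  min_share  min_mean_post
1      -7059.46     14198.79     14198.79     --        1.000          1.000
2      -6605.27     13322.35     13455.81    0.922      0.188          0.955
3      -6199.77     12543.28     12770.99    0.920      0.149          0.939
4      -6003.01     12181.71     12704.58    0.860      0.144          0.876
5      -5998.56     12204.76     13861.22    0.700      0.140          0.582
6      -5995.39     12230.36     14400.52    0.643      0.130          0.504
chosen G = 4
```

The estimated class shares (0.144, 0.162, 0.511, 0.183 after relabeling by
intake level: consistently high, low-to-moderate increasing, moderate
increasing, consistently low) recover the generating shares (0.151, 0.163,
0.506, 0.180) to within sampling error. The hazard stage then compares
baselines by AIC and reports hazard ratios against the consistently-low
class; on this cohort (193 events) the fully adjusted model gives:

```
model2: hazard ratios (weibull baseline)
 class  n_women  n_cases       HR   ci_low  ci_high  reference
     1      363       36 1.471521 0.881123 2.457517      False
     2      387       28 0.971734 0.557367 1.694155      False
     3     1306       99 1.088750 0.699916 1.693600      False
     4      450       30 1.000000      NaN      NaN       True
```

Class 1 here is the consistently-high class (generating HR 1.65, inside
the interval). With ~30 events per small class a single cohort of this
size is noisy — the log-HR standard error is ≈ 0.26 — which is why the
recovery experiments below average over replicates.

The same pipeline is available as a CLI (`alctraj simulate | run-all |
report | fit-lcmm | select | fit-hazard`) driven by one YAML config.

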