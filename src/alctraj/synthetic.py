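"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a prospective cohort of women aged 50-65 at
baseline with up to five alcohol-intake measures each (retrospective reports
at ages 20/30/40/50 plus one at baseline), a latent trajectory class per
woman, class-conditional covariates, and left-truncated, right-censored
breast-cancer event ages under class-specific proportional hazards.

The generative model mirrors the analysis model exactly:

* class ``g`` drawn from ``class_shares``;
* transformed intake ``y = x(t) @ beta_g + x(t) @ b + eps`` with
  ``x(t) = (1, t, t^2)``, ``t = (age - 35)/13``, subject random effects
  ``b ~ N(0, B)`` and residual ``eps ~ N(0, sigma^2)``;
* emitted intake ``max(exp(y) - 1, 0)`` grams/day (the inverse of the
  analysis transform ``log(x + 1)``, floored at zero since intakes cannot
  be negative);
* breast-cancer age from a Weibull proportional-hazards model,
  ``H(t | g) = (t / scale)^shape * exp(xi_g)``, sampled conditional on
  surviving event-free to the baseline age (inverse-transform on the
  conditional survival function), so every generated woman is cancer-free
  at entry and the configured number of subjects and class shares are
  preserved;
* competing censoring (death/emigration) exponential from entry, plus an
  administrative follow-up horizon.

Ground truth (class labels, random effects, uncensored event ages) is
returned separately and never read by any estimation code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from alctraj.preprocess import rescale_age, inverse_transform_intake

_COVARIATE_LEVELS = {
    "physical_activity": ["inactive", "moderately_inactive", "moderately_active", "active"],
    "smoking": ["never", "former", "smoker"],
    "education": ["primary", "technical_professional", "secondary", "higher"],
    "bmi_cat": ["lt18.5", "18.5-24.9", "25-29.9", "ge30"],
    "age_first_pregnancy": ["none", "le21", "22-26", "gt26"],
    "menarche": ["le12", "13-14", "gt14"],
    "breastfed": ["yes", "no"],
    "hrt_ever": ["yes", "no"],
}

# Class-conditional covariate distributions (rows = classes 1..4).  The
# contrasts follow the qualitative pattern seen in this kind of cohort:
# higher education and later first pregnancy more common in the
# consistently-high-intake class, never-smoking, inactivity, late menarche
# and high BMI more common in the consistently-low class.
_DEFAULT_COVARIATE_MODEL = {
    "education": [
        [0.361, 0.466, 0.092, 0.081],
        [0.192, 0.462, 0.183, 0.163],
        [0.287, 0.484, 0.122, 0.107],
        [0.491, 0.403, 0.060, 0.046],
    ],
    "smoking": [
        [0.451, 0.240, 0.309],
        [0.347, 0.289, 0.364],
        [0.432, 0.256, 0.312],
        [0.472, 0.208, 0.320],
    ],
    "physical_activity": [
        [0.103, 0.330, 0.259, 0.308],
        [0.104, 0.303, 0.257, 0.335],
        [0.096, 0.333, 0.251, 0.320],
        [0.143, 0.321, 0.217, 0.318],
    ],
    "bmi_cat": [
        [0.012, 0.496, 0.358, 0.135],
        [0.012, 0.555, 0.317, 0.116],
        [0.011, 0.518, 0.343, 0.129],
        [0.014, 0.421, 0.372, 0.193],
    ],
    "age_first_pregnancy": [
        [0.097, 0.342, 0.402, 0.159],
        [0.172, 0.223, 0.358, 0.248],
        [0.118, 0.271, 0.402, 0.209],
        [0.098, 0.381, 0.366, 0.155],
    ],
    "menarche": [
        [0.239, 0.480, 0.282],
        [0.239, 0.517, 0.244],
        [0.233, 0.498, 0.269],
        [0.229, 0.481, 0.291],
    ],
    "breastfed": [
        [0.843, 0.157],
        [0.765, 0.235],
        [0.825, 0.175],
        [0.830, 0.170],
    ],
    "hrt_ever": [
        [0.492, 0.508],
        [0.510, 0.490],
        [0.481, 0.519],
        [0.434, 0.566],
    ],
}


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort.

    Trajectory parameters (``class_fixed_effects``, ``re_covariance``,
    ``residual_sd``) live on the transformed log(x+1) intake scale with time
    t = (age - 35)/13.  Hazard parameters define a Weibull baseline for
    breast-cancer age (years) with class log hazard ratios relative to the
    reference class (log-HR 0).
    """

    n_subjects: int
    class_shares: tuple
    class_fixed_effects: tuple  # (G, 3) intercept/slope/quadratic per class
    re_covariance: tuple  # 3x3 PSD random-effect covariance
    residual_sd: float
    class_log_hr: tuple
    seed: int
    measure_ages: tuple = (20.0, 30.0, 40.0, 50.0)
    baseline_age_range: tuple = (50.0, 65.0)
    missing_rate: float = 0.005
    weibull_shape: float = 9.0
    weibull_scale: float = 100.0
    censor_rate: float = 0.01
    admin_followup_years: float = 17.0
    covariate_model: dict = field(default_factory=lambda: _DEFAULT_COVARIATE_MODEL)
    covariate_missing_rate: float = 0.073
    menopause_age_mean: float = 50.5
    menopause_age_sd: float = 3.0

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        shares = np.asarray(self.class_shares, dtype=float)
        if abs(shares.sum() - 1.0) > 1e-12:
            raise ValueError(f"class_shares must sum to 1, got {shares.sum()!r}")
        if np.any(shares < 0):
            raise ValueError("class_shares must be non-negative")
        beta = np.asarray(self.class_fixed_effects, dtype=float)
        if beta.shape != (self.n_classes, 3):
            raise ValueError("class_fixed_effects must be (G, 3)")
        B = np.asarray(self.re_covariance, dtype=float)
        if B.shape != (3, 3) or not np.allclose(B, B.T):
            raise ValueError("re_covariance must be symmetric 3x3")
        if np.min(np.linalg.eigvalsh(B)) < -1e-10:
            raise ValueError("re_covariance must be positive semi-definite")
        if len(self.class_log_hr) != self.n_classes:
            raise ValueError("class_log_hr length must equal number of classes")
        for name in ("residual_sd", "weibull_shape", "weibull_scale", "admin_followup_years"):
            if getattr(self, name) < 0 or (name != "residual_sd" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_shares"] = list(map(float, self.class_shares))
        d["class_fixed_effects"] = np.asarray(self.class_fixed_effects, dtype=float).tolist()
        d["re_covariance"] = np.asarray(self.re_covariance, dtype=float).tolist()
        d["class_log_hr"] = list(map(float, self.class_log_hr))
        d["measure_ages"] = list(map(float, self.measure_ages))
        d["baseline_age_range"] = list(map(float, self.baseline_age_range))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("class_shares", "class_log_hr", "measure_ages", "baseline_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("class_fixed_effects", "re_covariance"):
            if key in d:
                d[key] = tuple(tuple(row) for row in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Read a config from a YAML or JSON document; the seed must be present."""
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        if "seed" not in d:
            raise ValueError("config file must specify a seed")
        return cls.from_dict(d)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated cohort; never read by estimation code.

    Class labels are 1-based (1..G) to match the reporting convention.
    """

    class_label: np.ndarray
    random_effects: np.ndarray
    event_age_uncensored: np.ndarray
    config: GeneratorConfig

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "class_label": self.class_label.tolist(),
                "random_effects": self.random_effects.tolist(),
                "event_age_uncensored": self.event_age_uncensored.tolist(),
                "config": self.config.to_dict(),
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def default_config(n_subjects: int = 3000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Four-class default configuration.

    Class mean curves (natural scale): one low-to-moderate class rising in
    mid-adulthood (class 1), one consistently high class staying above
    10 g/day across ages 20-65 (class 2), one moderate class rising from a
    low intake in early adulthood (class 3, the majority), and one
    consistently low class below 6 g/day (class 4, the hazard reference).
    Shares default to (16.3%, 15.1%, 50.6%, 18.0%) and class hazard ratios
    to (1.18, 1.65, 1.15, 1).  The random-intercept variance is twice the
    residual variance, reflecting substantial within-class between-woman
    heterogeneity.
    """
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        class_shares=(0.163, 0.151, 0.506, 0.180),
        class_fixed_effects=(
            (1.50, 0.75, -0.10),
            (2.90, 0.25, -0.05),
            (1.85, 0.40, -0.12),
            (0.60, 0.10, -0.02),
        ),
        re_covariance=((0.09, 0.0, 0.0), (0.0, 0.01, 0.0), (0.0, 0.0, 0.0025)),
        residual_sd=0.212,
        class_log_hr=(float(np.log(1.18)), float(np.log(1.65)), float(np.log(1.15)), 0.0),
        seed=seed,
    )
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
    cfg.validate()
    return cfg


def _psd_sqrt(B: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (handles singular covariances)."""
    w, V = np.linalg.eigh(B)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _sample_categorical(rng, probs_by_class, classes0):
    probs = np.asarray(probs_by_class, dtype=float)
    probs = probs / probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)[classes0]  # (n, L)
    u = rng.uniform(size=len(classes0))
    return (u[:, None] > cum).sum(axis=1)


def generate_cohort(config: GeneratorConfig):
    """Generate one cohort: (intake records, subject profiles, ground truth).

    Returns
    -------
    intakes : pandas.DataFrame
        Long format: subject_id, age_years, intake_g_day, source.
    subjects : pandas.DataFrame
        One row per woman: baseline age, menstrual-history fields, the eight
        adjustment covariates, recruitment quintile, energy ratio, and
        entry/exit/event for the survival analysis.
    truth : SyntheticTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    G = config.n_classes
    beta = np.asarray(config.class_fixed_effects, dtype=float)
    B = np.asarray(config.re_covariance, dtype=float)

    classes0 = rng.choice(G, size=n, p=np.asarray(config.class_shares, dtype=float))
    b = rng.standard_normal((n, 3)) @ _psd_sqrt(B).T
    baseline_age = rng.uniform(*config.baseline_age_range, size=n)

    # --- intake measures -------------------------------------------------
    retro_ages = np.asarray(config.measure_ages, dtype=float)
    ages = np.column_stack([np.tile(retro_ages, (n, 1)), baseline_age])  # (n, m+1)
    t = rescale_age(ages)
    X = np.stack([np.ones_like(t), t, t * t], axis=-1)  # (n, m+1, 3)
    mean = np.einsum("nmk,nk->nm", X, beta[classes0] + b)
    y = mean + config.residual_sd * rng.standard_normal(mean.shape)
    intake = inverse_transform_intake(y)

    present = np.ones_like(intake, dtype=bool)
    if config.missing_rate > 0:
        present[:, : len(retro_ages)] = (
            rng.uniform(size=(n, len(retro_ages))) >= config.missing_rate
        )

    sources = [f"retro{int(a)}" for a in retro_ages] + ["baseline_ffq"]
    sid = np.arange(1, n + 1)
    intakes = pd.DataFrame(
        {
            "subject_id": np.repeat(sid, ages.shape[1]),
            "age_years": ages.ravel(),
            "intake_g_day": intake.ravel(),
            "source": np.tile(sources, n),
        }
    )[present.ravel()].reset_index(drop=True)

    # --- survival outcome ------------------------------------------------
    entry = baseline_age
    lin = np.asarray(config.class_log_hr, dtype=float)[classes0]
    H_entry = (entry / config.weibull_scale) ** config.weibull_shape
    # conditional on being event-free at entry: H(T) = H(E) + Exp(1)/exp(xi)
    H_event = H_entry + rng.exponential(size=n) / np.exp(lin)
    event_age = config.weibull_scale * H_event ** (1.0 / config.weibull_shape)
    if config.censor_rate > 0:
        censor_age = entry + rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor_age = np.full(n, np.inf)
    admin_age = entry + config.admin_followup_years
    exit_age = np.minimum.reduce([event_age, censor_age, admin_age])
    event = (event_age <= censor_age) & (event_age <= admin_age)

    # --- menstrual history ----------------------------------------------
    menopause_age = rng.normal(config.menopause_age_mean, config.menopause_age_sd, size=n)
    years_since = baseline_age - menopause_age
    months = np.where(years_since > 0, np.round(years_since * 12), 0.0)
    menstruating = years_since <= 0
    periods = np.where(menstruating, 12.0, np.where(years_since < 1, 6.0, 0.0))
    ovariectomy = rng.uniform(size=n) < 0.02
    hysterectomy = rng.uniform(size=n) < 0.08
    hormone_use = rng.uniform(size=n) < 0.05
    history_missing = rng.uniform(size=n) < 0.01

    months_col = months.astype(float)
    periods_col = periods.astype(float)
    menstr_col = menstruating.astype(float)
    months_col[history_missing] = np.nan
    periods_col[history_missing] = np.nan
    menstr_col[history_missing] = np.nan

    subjects = pd.DataFrame(
        {
            "subject_id": sid,
            "baseline_age": baseline_age,
            "months_since_last_menses": months_col,
            "periods_last_year": periods_col,
            "menstruating_at_baseline": menstr_col,
            "bilateral_ovariectomy": ovariectomy.astype(int),
            "hysterectomy": hysterectomy.astype(int),
            "exogenous_hormone_use": hormone_use.astype(int),
            "recruitment_quintile": rng.integers(1, 6, size=n),
            "energy_ratio": np.exp(rng.normal(0.0, 0.2, size=n)),
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event.astype(int),
        }
    )

    for cov, levels in _COVARIATE_LEVELS.items():
        probs = config.covariate_model[cov]
        idx = _sample_categorical(rng, probs, classes0)
        subjects[cov] = pd.Categorical.from_codes(idx, categories=levels)

    if config.covariate_missing_rate > 0:
        cov_names = list(_COVARIATE_LEVELS)
        hit = rng.uniform(size=n) < config.covariate_missing_rate
        which = rng.integers(0, len(cov_names), size=n)
        for j, cov in enumerate(cov_names):
            mask = hit & (which == j)
            if mask.any():
                subjects.loc[mask, cov] = np.nan

    truth = SyntheticTruth(
        class_label=classes0 + 1,
        random_effects=b,
        event_age_uncensored=event_age,
        config=config,
    )
    return intakes, subjects, truth


def truth_lcmm_fit(config: GeneratorConfig):
    """Express the generator's trajectory truth in the estimation parameterization.

    Used to initialize recovery experiments at the true parameter values and
    to compute reference posteriors; it is an explicit bridge, not something
    any estimation routine consults on its own.
    """
    from alctraj.lcmm import LcmmFit

    shares = np.asarray(config.class_shares, dtype=float)
    B = np.asarray(config.re_covariance, dtype=float)
    w, V = np.linalg.eigh(B)
    B_pd = (V * np.clip(w, 1e-12, None)) @ V.T
    return LcmmFit(
        n_classes=config.n_classes,
        beta=np.asarray(config.class_fixed_effects, dtype=float).copy(),
        membership_logits=np.log(shares[:-1]) - np.log(shares[-1]),
        re_cholesky=np.linalg.cholesky(B_pd),
        residual_sd=config.residual_sd,
    )


def write_cohort(intakes, subjects, truth, out_dir) -> dict:
    """Write intakes.csv, subjects.csv and truth.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intakes": out / "intakes.csv",
        "subjects": out / "subjects.csv",
        "truth": out / "truth.json",
    }
    intakes.to_csv(paths["intakes"], index=False)
    subjects.to_csv(paths["subjects"], index=False)
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
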