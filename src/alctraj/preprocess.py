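"""Cohort assembly: beverage quantification, exclusion flow, menopausal status, transforms.

The trajectory analysis runs on the log(x+1)-transformed ethanol intake
(grams/day) as a quadratic function of rescaled age t = (age - 35) / 13.
This module owns those transforms, the beverage-frequency -> grams/day
conversion, the menopausal-status rule cascade used to restrict the survival
analysis to postmenopausal women, and the ordered exclusion flow that turns
raw intake/subject tables into the trajectory and survival analysis sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Ethanol content per serving, grams.  One bottle of beer is 330 ml, wine is
# a 125 ml glass, fortified wine a 60 ml drink, spirits a 30 ml drink.
ETHANOL_G_PER_SERVING: dict[str, float] = {
    "light_beer": 8.9,
    "regular_beer": 12.2,
    "strong_beer": 17.5,
    "wine": 12.5,
    "fortified_wine": 9.3,
    "spirits": 9.9,
}

# Consumption-frequency categories ("never" up to ">= 8 times per day")
# mapped to servings/day via category midpoints; the open top category maps
# to 8.  Months are taken as 30 days, weeks as 7.
FREQUENCY_CATEGORY_SERVINGS_PER_DAY: dict[str, float] = {
    "never": 0.0,
    "lt_1_per_month": 0.5 / 30.0,
    "1_per_month": 1.0 / 30.0,
    "2_3_per_month": 2.5 / 30.0,
    "1_per_week": 1.0 / 7.0,
    "2_4_per_week": 3.0 / 7.0,
    "5_6_per_week": 5.5 / 7.0,
    "1_per_day": 1.0,
    "2_3_per_day": 2.5,
    "4_5_per_day": 4.5,
    "6_7_per_day": 6.5,
    "8_plus_per_day": 8.0,
}

#: Covariates required complete for the fully adjusted survival model.
MODEL2_COVARIATES: tuple[str, ...] = (
    "physical_activity",
    "smoking",
    "education",
    "bmi_cat",
    "age_first_pregnancy",
    "menarche",
    "breastfed",
    "hrt_ever",
)

AGE_CENTER_YEARS = 35.0
AGE_SCALE_YEARS = 13.0

INTAKE_SOURCES = ("retro20", "retro30", "retro40", "retro50", "baseline_ffq")


def frequency_to_grams(freqs: dict[str, float]) -> float:
    """Convert per-beverage serving frequencies (servings/day) to grams ethanol/day.

    Parameters
    ----------
    freqs
        Mapping from beverage name (a key of :data:`ETHANOL_G_PER_SERVING`)
        to servings per day.  Missing beverages count as zero.

    Returns
    -------
    float
        Total grams of ethanol per day, ``sum_b freq_b * grams_b``.
    """
    total = 0.0
    for beverage, freq in freqs.items():
        if beverage not in ETHANOL_G_PER_SERVING:
            raise KeyError(f"unknown beverage {beverage!r}")
        if freq < 0:
            raise ValueError(f"negative frequency for {beverage!r}: {freq}")
        total += freq * ETHANOL_G_PER_SERVING[beverage]
    return total


def servings_per_day(category: str) -> float:
    """Servings/day midpoint for one of the 12 reported frequency categories."""
    try:
        return FREQUENCY_CATEGORY_SERVINGS_PER_DAY[category]
    except KeyError:
        raise KeyError(
            f"unknown frequency category {category!r}; expected one of "
            f"{sorted(FREQUENCY_CATEGORY_SERVINGS_PER_DAY)}"
        ) from None


def transform_intake(x):
    """log(x + 1) transform of grams/day intake; rejects negative input."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intake must be non-negative")
    out = np.log1p(x)
    return float(out) if out.ndim == 0 else out


def inverse_transform_intake(y):
    """Back-transform a modelled value to grams/day: max(exp(y) - 1, 0)."""
    y = np.asarray(y, dtype=float)
    out = np.maximum(np.expm1(y), 0.0)
    return float(out) if out.ndim == 0 else out


def rescale_age(age_years):
    """Rescale and recentre age in years to the unitless model time t = (age - 35) / 13."""
    age_years = np.asarray(age_years, dtype=float)
    out = (age_years - AGE_CENTER_YEARS) / AGE_SCALE_YEARS
    return float(out) if out.ndim == 0 else out


def unscale_age(t):
    """Inverse of :func:`rescale_age`: years = 35 + 13 t."""
    t = np.asarray(t, dtype=float)
    out = AGE_CENTER_YEARS + AGE_SCALE_YEARS * t
    return float(out) if out.ndim == 0 else out


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def classify_menopause(
    baseline_age: float,
    months_since_last_menses=None,
    periods_last_year=None,
    menstruating_at_baseline=None,
    bilateral_ovariectomy: bool = False,
    hysterectomy: bool = False,
    exogenous_hormone_use: bool = False,
) -> str:
    """Classify baseline menopausal status as ``"pre"``, ``"peri"`` or ``"post"``.

    The rule cascade, applied in order:

    1. *post* if no menses for >= 12 months, or bilateral ovariectomy.
    2. If menstrual history is missing, or the woman had a hysterectomy or
       used exogenous hormones: *post* if aged >= 55, *peri* if aged 46-55,
       otherwise *pre*.  At exactly 55 the ">= 55" clause wins.
    3. *peri* if < 9 menstrual periods in the preceding year, or if she
       menstruated within the past year but not at baseline.
    4. Otherwise *pre*.
    """
    if _is_missing(baseline_age):
        raise ValueError("baseline_age is required")

    if bilateral_ovariectomy:
        return "post"
    if not _is_missing(months_since_last_menses) and months_since_last_menses >= 12:
        return "post"

    history_missing = (
        _is_missing(months_since_last_menses)
        and _is_missing(periods_last_year)
        and _is_missing(menstruating_at_baseline)
    )
    if history_missing or hysterectomy or exogenous_hormone_use:
        if baseline_age >= 55:
            return "post"
        if 46 <= baseline_age <= 55:
            return "peri"
        return "pre"

    if not _is_missing(periods_last_year) and periods_last_year < 9:
        return "peri"
    menstruated_past_year = (
        not _is_missing(months_since_last_menses) and months_since_last_menses < 12
    )
    if menstruated_past_year and menstruating_at_baseline is not None and not menstruating_at_baseline:
        return "peri"
    return "pre"


def classify_menopause_frame(subjects: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_menopause` over a subject table."""

    def one(row):
        return classify_menopause(
            baseline_age=row["baseline_age"],
            months_since_last_menses=row.get("months_since_last_menses"),
            periods_last_year=row.get("periods_last_year"),
            menstruating_at_baseline=_coerce_flag(row.get("menstruating_at_baseline")),
            bilateral_ovariectomy=bool(_coerce_flag(row.get("bilateral_ovariectomy")) or False),
            hysterectomy=bool(_coerce_flag(row.get("hysterectomy")) or False),
            exogenous_hormone_use=bool(_coerce_flag(row.get("exogenous_hormone_use")) or False),
        )

    return subjects.apply(one, axis=1)


def _coerce_flag(value):
    if _is_missing(value):
        return None
    return bool(value)


def recode_peri_as_post(status: str) -> str:
    """Recode perimenopausal to postmenopausal; pre and post pass through."""
    if status not in ("pre", "peri", "post"):
        raise ValueError(f"invalid menopausal status {status!r}")
    return "post" if status == "peri" else status


def exclude_energy_ratio_extremes(ratios: pd.Series):
    """Drop subjects in the extreme 1% tails of the energy intake / requirement ratio.

    Subjects strictly below the 1st or strictly above the 99th empirical
    percentile (linear interpolation) are excluded; ties at the cut values
    are retained.

    Parameters
    ----------
    ratios
        EI/ER ratio indexed by subject id.  Missing values are excluded up
        front and reported in the log entry.

    Returns
    -------
    (retained_index, log_entry)
        Index of retained subject ids and a dict describing the step.
    """
    finite = ratios[np.isfinite(ratios.astype(float))]
    if finite.empty:
        raise ValueError("no finite energy-ratio values")
    lo, hi = np.percentile(finite.to_numpy(dtype=float), [1.0, 99.0])
    keep = finite[(finite >= lo) & (finite <= hi)]
    log_entry = {
        "step": "energy_ratio_1pct_trim",
        "cut_low": float(lo),
        "cut_high": float(hi),
        "excluded_n": int(len(ratios) - len(keep)),
        "remaining_n": int(len(keep)),
    }
    return keep.index, log_entry


@dataclass
class FlowReport:
    """Ordered accounting of cohort exclusions.

    Each step records how many subjects were removed and how many remain, so
    that ``initial_n - sum(excluded) == final_n`` always holds.
    """

    initial_n: int
    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, excluded_n: int) -> int:
        remaining = self.remaining_n - int(excluded_n)
        if remaining < 0:
            raise ValueError(f"step {step!r} excludes more subjects than remain")
        self.steps.append(
            {"step": step, "excluded_n": int(excluded_n), "remaining_n": remaining}
        )
        return remaining

    @property
    def remaining_n(self) -> int:
        return self.steps[-1]["remaining_n"] if self.steps else self.initial_n

    @property
    def total_excluded(self) -> int:
        return sum(s["excluded_n"] for s in self.steps)

    def check(self) -> None:
        """Assert the accounting identity initial - sum(excluded) = final."""
        if self.initial_n - self.total_excluded != self.remaining_n:
            raise AssertionError("flow accounting identity violated")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"initial_n": self.initial_n, "steps": self.steps, "final_n": self.remaining_n},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def flow_accounting(initial_n: int, exclusions: list[tuple[str, int]]) -> FlowReport:
    """Build a :class:`FlowReport` from an initial count and ordered (step, n) exclusions."""
    report = FlowReport(initial_n=int(initial_n))
    for step, n in exclusions:
        report.add(step, n)
    report.check()
    return report


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count`` in ``total`` rounded to ``decimals`` (table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def assemble_analysis_sets(
    intakes: pd.DataFrame,
    subjects: pd.DataFrame,
    energy_ratio_col: str = "energy_ratio",
    apply_energy_trim: bool = True,
):
    """Assemble the trajectory and survival analysis sets with a flow report.

    The trajectory set keeps every woman passing the cohort-level exclusions
    (here the 1% energy-ratio trim) irrespective of menopausal status or
    covariate completeness; it feeds the latent-class trajectory model.  The
    survival set additionally drops premenopausal women (after recoding
    peri as post) and women missing any fully-adjusted-model covariate
    (complete-case analysis).

    Returns
    -------
    (trajectory_subjects, survival_subjects, flow_report)
    """
    if subjects["subject_id"].duplicated().any():
        dups = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject ids: {dups[:5]}")
    if not set(intakes["subject_id"]).issubset(set(subjects["subject_id"])):
        raise ValueError("intake records reference unknown subject ids")

    report = FlowReport(initial_n=len(subjects))
    current = subjects.set_index("subject_id", drop=False)

    if apply_energy_trim and energy_ratio_col in current.columns:
        keep_idx, _ = exclude_energy_ratio_extremes(current[energy_ratio_col])
        excluded = len(current) - len(keep_idx)
        current = current.loc[keep_idx]
        report.add("energy_ratio_1pct_trim", excluded)

    trajectory_subjects = current.reset_index(drop=True)

    status = classify_menopause_frame(current).map(recode_peri_as_post)
    n_pre = int((status == "pre").sum())
    current = current.loc[status != "pre"]
    report.add("premenopausal_at_baseline", n_pre)

    missing_any = current[list(MODEL2_COVARIATES)].isna().any(axis=1)
    n_missing = int(missing_any.sum())
    current = current.loc[~missing_any]
    report.add("missing_model2_covariates", n_missing)

    report.check()
    survival_subjects = current.reset_index(drop=True)
    return trajectory_subjects, survival_subjects, report
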