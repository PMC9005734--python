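"""Longitudinal dose–response analysis of microvascular metrics.

Per-subject metric time series (tidy table: subject_id, dose_Gy, day,
metric, value) are normalized to their pre-irradiation baseline —
DLF_150 as the ratio DLF_150(t)/DLF_150(0), λ as the difference
Δλ(t) = λ(t) − λ(0) — then compared across dose cohorts at matched
timepoints with one-way ANOVA followed by per-dose Welch t-tests against
the unirradiated controls.  No multiple-testing correction is applied;
p < 0.05 is the conventional significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LongitudinalSeries",
    "CohortComparison",
    "normalize_to_baseline",
    "delta_from_baseline",
    "normalize_dlf",
    "delta_lambda",
    "cohort_compare",
    "cohort_summary",
    "time_to_peak",
    "TIDY_COLUMNS",
]

TIDY_COLUMNS = ["subject_id", "dose_Gy", "day", "metric", "value"]

CONTROL_DOSE = 0.0


@dataclass
class LongitudinalSeries:
    """Time-ordered metric values for one subject.

    ``days`` must be strictly increasing and include day 0 (the
    pre-irradiation baseline used for normalization).
    """

    subject_id: str
    dose_Gy: float
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must have the same length")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if self.days.size == 0 or self.days[0] != 0:
            raise ValueError("series must start at day 0 (baseline)")


@dataclass
class CohortComparison:
    """ANOVA across cohorts plus pairwise dose-vs-control t-tests."""

    metric: str
    day: float
    anova_p: float
    pairwise_p: dict[float, float]  # dose → p vs control
    n_per_cohort: dict[float, int] = field(default_factory=dict)
    equal_var: bool = False


def normalize_to_baseline(values: np.ndarray) -> np.ndarray:
    """Element-wise ratio to the first (baseline) value; first entry 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if values[0] == 0:
        raise ValueError("zero baseline: ratio normalization undefined")
    return values / values[0]


def delta_from_baseline(values: np.ndarray) -> np.ndarray:
    """Element-wise difference from the first (baseline) value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if not np.isfinite(values[0]):
        raise ValueError("baseline value is not finite")
    return values - values[0]


def _normalize_tidy(df: pd.DataFrame, metric: str, func, out_metric: str) -> pd.DataFrame:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy table missing columns {missing}")
    sub = df[df["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    out = []
    for (subject, dose), grp in sub.groupby(["subject_id", "dose_Gy"], sort=True):
        grp = grp.sort_values("day")
        if grp["day"].iloc[0] != 0:
            raise ValueError(f"subject {subject!r} has no day-0 baseline")
        vals = func(grp["value"].to_numpy())
        out.append(
            pd.DataFrame(
                {
                    "subject_id": subject,
                    "dose_Gy": dose,
                    "day": grp["day"].to_numpy(),
                    "metric": out_metric,
                    "value": vals,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def normalize_dlf(df: pd.DataFrame, metric: str = "DLF_150") -> pd.DataFrame:
    """Per-subject ratio normalization DLF(t)/DLF(0) of a tidy table."""
    return _normalize_tidy(df, metric, normalize_to_baseline, f"{metric}_ratio")


def delta_lambda(df: pd.DataFrame, metric: str = "lambda") -> pd.DataFrame:
    """Per-subject baseline subtraction Δλ(t) = λ(t) − λ(0)."""
    return _normalize_tidy(df, metric, delta_from_baseline, f"delta_{metric}")


def _nearest_day(days: np.ndarray, target: float, tolerance: float) -> float:
    i = int(np.argmin(np.abs(days - target)))
    if abs(days[i] - target) > tolerance:
        raise ValueError(
            f"no stored visit within ±{tolerance} days of day {target} "
            f"(nearest: {days[i]})"
        )
    return float(days[i])


def cohort_compare(
    df: pd.DataFrame,
    metric: str,
    day: float,
    control_dose: float = CONTROL_DOSE,
    tolerance_days: float = 2.0,
    equal_var: bool = False,
) -> CohortComparison:
    """One-way ANOVA across dose cohorts at a timepoint, then per-dose
    two-sample t-tests against the control cohort.

    Visits are matched per subject to the nearest stored day within
    ``tolerance_days`` (subjects are imaged every few days on
    unsynchronized schedules).  Welch's unequal-variance t-test is the
    default; set ``equal_var=True`` for the pooled variant.  All
    p-values are returned regardless of the ANOVA outcome so the caller
    applies the screening convention explicitly.
    """
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    samples: dict[float, np.ndarray] = {}
    for dose, grp in sub.groupby("dose_Gy"):
        vals = []
        for _, s in grp.groupby("subject_id"):
            days = s["day"].to_numpy(dtype=float)
            d = _nearest_day(days, day, tolerance_days)
            vals.append(float(s.loc[s["day"] == d, "value"].iloc[0]))
        samples[float(dose)] = np.asarray(vals)
    if len(samples) < 2:
        raise ValueError("need at least two cohorts")
    if any(v.size < 2 for v in samples.values()):
        raise ValueError("every cohort needs n >= 2")
    if control_dose not in samples:
        raise ValueError(f"control cohort (dose {control_dose} Gy) not present")
    anova = stats.f_oneway(*samples.values())
    pairwise = {}
    for dose, vals in samples.items():
        if dose == control_dose:
            continue
        t = stats.ttest_ind(vals, samples[control_dose], equal_var=equal_var)
        pairwise[dose] = float(t.pvalue)
    return CohortComparison(
        metric=metric,
        day=day,
        anova_p=float(anova.pvalue),
        pairwise_p=pairwise,
        n_per_cohort={d: int(v.size) for d, v in samples.items()},
        equal_var=equal_var,
    )


def cohort_summary(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean, SD and n per dose × day for one metric (SD reported only
    for n ≥ 2)."""
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    out = (
        sub.groupby(["dose_Gy", "day"])["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def time_to_peak(
    days: np.ndarray, values: np.ndarray, direction: str = "max"
) -> float:
    """Day of the extremum of a response series (max for DLF/λ ratios,
    min for volume-like series).  Ties break to the earliest day; an
    all-equal series has no peak and raises."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ValueError("days and values must have the same length")
    if days.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.allclose(values, values[0]):
        raise ValueError("all-equal series: time to peak undefined")
    if direction == "max":
        i = int(np.argmax(values))
    elif direction == "min":
        i = int(np.argmin(values))
    else:
        raise ValueError("direction must be 'max' or 'min'")
    return float(days[i])
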