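"""Phenotype derivation: activity index, BMI categories, exclusion rules."""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .errors import DataError, PipelineError, VocabularyError

OCCUPATIONS = ("sedentary", "standing", "physical", "heavy")

#: Required baseline phenotype columns (missingness triggers exclusion).
REQUIRED_BASELINE = ("sex", "age", "bmi_baseline", "waist_baseline", "occupation")

ANNUAL_BMI_CHANGE_MAX = 2.0  # kg/m^2 per year
ANNUAL_WAIST_CHANGE_MAX = 7.0  # cm per year


class ActivityLevel(IntEnum):
    INACTIVE = 0
    MODERATELY_INACTIVE = 1
    MODERATELY_ACTIVE = 2
    ACTIVE = 3


def classify_activity(occupation: str, recreation_hours_per_day: float) -> ActivityLevel:
    """Four-level physical-activity index from occupation and daily recreation.

    sedentary: 0 h -> inactive; (0, 0.5) -> moderately inactive;
    [0.5, 1.0] -> moderately active; >1 -> active.
    standing: 0 -> moderately inactive; (0, 0.5) -> moderately active;
    >=0.5 -> active.
    physical: 0 -> moderately active; >0 -> active.
    heavy: always active.

    The sedentary upper bound of the moderately-active band is inclusive
    at both ends and standing >=0.5 maps to active; this fills the
    undocumented standing 0.5-1.0 cell monotonically.
    """
    if occupation not in OCCUPATIONS:
        raise VocabularyError(
            f"unknown occupation {occupation!r}; expected one of {OCCUPATIONS}"
        )
    h = float(recreation_hours_per_day)
    if h < 0:
        raise DataError(f"recreation hours must be >= 0, got {h}")
    if occupation == "sedentary":
        if h == 0:
            return ActivityLevel.INACTIVE
        if h < 0.5:
            return ActivityLevel.MODERATELY_INACTIVE
        if h <= 1.0:
            return ActivityLevel.MODERATELY_ACTIVE
        return ActivityLevel.ACTIVE
    if occupation == "standing":
        if h == 0:
            return ActivityLevel.MODERATELY_INACTIVE
        if h < 0.5:
            return ActivityLevel.MODERATELY_ACTIVE
        return ActivityLevel.ACTIVE
    if occupation == "physical":
        return ActivityLevel.MODERATELY_ACTIVE if h == 0 else ActivityLevel.ACTIVE
    return ActivityLevel.ACTIVE  # heavy


def classify_activity_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_activity` over a phenotype table."""
    occ = records["occupation"]
    bad = ~occ.isin(OCCUPATIONS) & occ.notna()
    if bad.any():
        raise VocabularyError(
            f"unknown occupation value(s): {sorted(occ[bad].unique())}"
        )
    h = records["recreation_hours_per_day"].to_numpy(dtype=float)
    if np.nanmin(h, initial=0.0) < 0:
        raise DataError("recreation hours must be >= 0")
    occ = occ.to_numpy(dtype=object)
    level = np.full(len(records), -1, dtype=float)

    sed = occ == "sedentary"
    level[sed & (h == 0)] = 0
    level[sed & (h > 0) & (h < 0.5)] = 1
    level[sed & (h >= 0.5) & (h <= 1.0)] = 2
    level[sed & (h > 1.0)] = 3
    sta = occ == "standing"
    level[sta & (h == 0)] = 1
    level[sta & (h > 0) & (h < 0.5)] = 2
    level[sta & (h >= 0.5)] = 3
    phy = occ == "physical"
    level[phy & (h == 0)] = 2
    level[phy & (h > 0)] = 3
    level[occ == "heavy"] = 3

    level[np.isnan(h) | pd.isna(records["occupation"]).to_numpy()] = np.nan
    # heavy jobs classify without recreation hours
    level[(occ == "heavy")] = 3
    return pd.Series(level, index=records.index, name="activity")


def weekly_to_daily(hours_summer: float, hours_winter: float) -> float:
    """Average the seasonal weekly activity totals and convert to hours/day."""
    if hours_summer < 0 or hours_winter < 0:
        raise DataError("weekly activity hours must be >= 0")
    return (hours_summer + hours_winter) / 2.0 / 7.0


def annual_change(value_baseline, value_followup, followup_years):
    """(follow-up - baseline) / years; NaN when follow-up is missing."""
    baseline = np.asarray(value_baseline, dtype=float)
    followup = np.asarray(value_followup, dtype=float)
    years = np.asarray(followup_years, dtype=float)
    if np.any(years[~np.isnan(years)] <= 0):
        raise DataError("followup_years must be > 0 where present")
    with np.errstate(invalid="ignore"):
        out = (followup - baseline) / years
    if out.ndim == 0:
        return float(out)
    return out


def bmi_category(bmi: float) -> str:
    """WHO cut-points; 'overweight_only' is the 25 <= BMI < 30 band."""
    if np.isnan(bmi):
        raise DataError("BMI is missing")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight_only"
    return "obese"


def apply_exclusions(
    records: pd.DataFrame,
    exclude_cvd_cancer: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort exclusion rules in their declared order.

    Rules, applied sequentially (a subject is counted under the first
    rule that removes it):

    1. prevalent type 2 diabetes;
    2. missing any required baseline phenotype (recreation hours count
       as required unless the occupation is heavy, which classifies
       without them);
    3. absolute annual BMI change > 2 kg/m^2/y or waist change > 7 cm/y,
       testable only where follow-up exists (baseline-only subjects pass
       vacuously);
    4. (optional sensitivity) prevalent cardiovascular disease or cancer.

    Returns the analysis set and a report with one row per rule
    (rule, n_excluded, order).
    """
    df = records.copy()
    report_rows = []
    order = 0

    def _drop(mask: pd.Series, rule: str) -> None:
        nonlocal df, order
        order += 1
        n = int(mask.sum())
        report_rows.append({"rule": rule, "n_excluded": n, "order": order})
        df = df.loc[~mask]

    _drop(df["prevalent_t2d"].fillna(0).astype(float) == 1, "prevalent_t2d")

    missing = pd.Series(False, index=df.index)
    for col in REQUIRED_BASELINE:
        missing |= df[col].isna()
    hours_needed = df["occupation"].ne("heavy") | df["occupation"].isna()
    missing |= hours_needed & df["recreation_hours_per_day"].isna()
    _drop(missing, "missing_baseline_phenotype")

    d_bmi = annual_change(df["bmi_baseline"], df["bmi_followup"], df["followup_years"])
    d_waist = annual_change(
        df["waist_baseline"], df["waist_followup"], df["followup_years"]
    )
    implausible = (np.abs(d_bmi) > ANNUAL_BMI_CHANGE_MAX) | (
        np.abs(d_waist) > ANNUAL_WAIST_CHANGE_MAX
    )
    implausible = pd.Series(np.nan_to_num(implausible.astype(float)) == 1, index=df.index)
    _drop(implausible, "implausible_annual_change")

    if exclude_cvd_cancer:
        cvd = df.get("prevalent_cvd", pd.Series(0, index=df.index))
        cancer = df.get("prevalent_cancer", pd.Series(0, index=df.index))
        flagged = (cvd.fillna(0).astype(float) == 1) | (
            cancer.fillna(0).astype(float) == 1
        )
        _drop(flagged, "prevalent_cvd_or_cancer")

    if df.empty:
        raise PipelineError("exclusions removed every subject")
    report = pd.DataFrame.from_records(report_rows)
    return df, report


def derive_analysis_columns(records: pd.DataFrame) -> pd.DataFrame:
    """Attach activity level, annual changes, and BMI category flags."""
    df = records.copy()
    df["activity"] = classify_activity_frame(df)
    df["annual_bmi_change"] = annual_change(
        df["bmi_baseline"], df["bmi_followup"], df["followup_years"]
    )
    bmi = df["bmi_baseline"]
    df["obese"] = (bmi >= 30).astype(int)
    df["normal_weight"] = ((bmi >= 18.5) & (bmi < 25)).astype(int)
    df["overweight"] = (bmi >= 25).astype(int)
    return df
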