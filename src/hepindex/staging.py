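"""Elastography-based staging and cohort eligibility screening.

Steatosis is graded from the controlled attenuation parameter (CAP,
dB/m) and fibrosis staged from vibration-controlled transient
elastography (VCTE) liver stiffness (kPa), using biopsy-validated
thresholds for steatotic liver disease:

* steatosis: S1 ≥ 294, S2 ≥ 310, S3 ≥ 331 dB/m (S2–S3 = significant)
* fibrosis:  F2 ≥ 8.2, F3 ≥ 9.7, F4 ≥ 13.6 kPa (F3–F4 = severe)

All thresholds are lower-bound inclusive.  A VCTE examination is
considered reliable when the IQR/median ratio of the stiffness readings
is below 30% and at least 10 valid readings were obtained.

Eligibility implements the MASLD consensus screen: steatosis evidence
(ultrasound and/or CAP > 248 dB/m) plus at least one criterion of
metabolic dysfunction (BMI ≥ 25, type-2 diabetes, or ≥ 2 of five
metabolic risk factors).  Controls require absence of steatosis by both
modalities (CAP < 248), BMI < 25, no diabetes and at most one risk
factor.  Note the eligibility screen (248 dB/m) and the severity grading
(294 dB/m) deliberately use different CAP scales: a subject can qualify
as MASLD yet grade S0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Optional

import numpy as np
import pandas as pd

from .indices import SubjectRecord

__all__ = [
    "SteatosisGrade",
    "FibrosisStage",
    "EligibilityLabel",
    "STEATOSIS_THRESHOLDS",
    "FIBROSIS_THRESHOLDS",
    "grade_steatosis",
    "stage_fibrosis",
    "grade_steatosis_array",
    "stage_fibrosis_array",
    "is_reliable_vcte",
    "count_metabolic_risk_factors",
    "classify_eligibility",
    "stage_table",
]

from ._defaults import DEFAULTS

_STAGING = DEFAULTS["staging"]

STEATOSIS_GRADES = ("S0", "S1", "S2", "S3")
FIBROSIS_STAGES = ("F0F1", "F2", "F3", "F4")

#: CAP lower bounds (dB/m) for S1, S2, S3
STEATOSIS_THRESHOLDS = tuple(_STAGING["steatosis_cap_thresholds"])
#: stiffness lower bounds (kPa) for F2, F3, F4
FIBROSIS_THRESHOLDS = tuple(_STAGING["fibrosis_te_thresholds"])

CAP_RANGE = tuple(_STAGING["cap_device_range"])
TE_RANGE = tuple(_STAGING["te_device_range"])

#: CAP screen (dB/m) separating steatosis evidence (>) from its absence (<)
CAP_STEATOSIS_SCREEN = float(_STAGING["cap_steatosis_screen"])

VCTE_MAX_IQR_OVER_MEDIAN = float(_STAGING["vcte_max_iqr_over_median"])
VCTE_MIN_VALID_READINGS = int(_STAGING["vcte_min_valid_readings"])
DEFAULT_AST_ALT_ULN = float(_STAGING["ast_alt_uln"])


@dataclass(frozen=True)
class SteatosisGrade:
    grade: Literal["S0", "S1", "S2", "S3"]
    significant: bool  # S2–S3

    @property
    def ordinal(self) -> int:
        return STEATOSIS_GRADES.index(self.grade)


@dataclass(frozen=True)
class FibrosisStage:
    stage: Literal["F0F1", "F2", "F3", "F4"]
    severe: bool  # F3–F4

    @property
    def ordinal(self) -> int:
        return FIBROSIS_STAGES.index(self.stage)


@dataclass(frozen=True)
class EligibilityLabel:
    label: Literal["masld", "control", "ineligible"]
    reasons: List[str] = field(default_factory=list)


def grade_steatosis(cap: float) -> SteatosisGrade:
    """Grade steatosis from CAP (dB/m); thresholds lower-bound inclusive."""
    lo, hi = CAP_RANGE
    if not (lo <= cap <= hi):
        raise ValueError(f"cap outside device range [{lo}, {hi}] dB/m: {cap}")
    idx = int(np.searchsorted(STEATOSIS_THRESHOLDS, cap, side="right"))
    grade = STEATOSIS_GRADES[idx]
    return SteatosisGrade(grade=grade, significant=idx >= 2)


def stage_fibrosis(te: float) -> FibrosisStage:
    """Stage fibrosis from liver stiffness (kPa); lower-bound inclusive."""
    lo, hi = TE_RANGE
    if not (lo <= te <= hi):
        raise ValueError(f"te outside device range [{lo}, {hi}] kPa: {te}")
    idx = int(np.searchsorted(FIBROSIS_THRESHOLDS, te, side="right"))
    return FibrosisStage(stage=FIBROSIS_STAGES[idx], severe=idx >= 2)


def grade_steatosis_array(cap: np.ndarray) -> np.ndarray:
    """Ordinal steatosis grade (0–3) for an array of CAP values; NaN → -1."""
    cap = np.asarray(cap, float)
    out = np.searchsorted(STEATOSIS_THRESHOLDS, cap, side="right")
    return np.where(np.isnan(cap), -1, out).astype(int)


def stage_fibrosis_array(te: np.ndarray) -> np.ndarray:
    """Ordinal fibrosis stage (0–3) for an array of stiffness values; NaN → -1."""
    te = np.asarray(te, float)
    out = np.searchsorted(FIBROSIS_THRESHOLDS, te, side="right")
    return np.where(np.isnan(te), -1, out).astype(int)


def is_reliable_vcte(iqr_over_median: float, valid_count: int) -> bool:
    """True iff IQR/median < 0.30 (strict) and ≥ 10 valid readings."""
    if iqr_over_median < 0 or valid_count < 0:
        raise ValueError("iqr_over_median and valid_count must be non-negative")
    return (
        iqr_over_median < VCTE_MAX_IQR_OVER_MEDIAN
        and valid_count >= VCTE_MIN_VALID_READINGS
    )


def count_metabolic_risk_factors(record: SubjectRecord) -> int:
    """Count the five consensus metabolic risk factors that are satisfied.

    Boundaries are inclusive; absent optional fields count as
    criterion-not-met.
    """
    r = record
    male = r.sex == "male"
    n = 0
    # 1. central obesity
    if r.waist_circumference is not None and r.waist_circumference >= (
        102.0 if male else 88.0
    ):
        n += 1
    # 2. blood pressure or treatment
    bp = (
        (r.systolic_bp is not None and r.systolic_bp >= 130.0)
        or (r.diastolic_bp is not None and r.diastolic_bp >= 85.0)
    )
    if bp or r.on_antihypertensives:
        n += 1
    # 3. triglycerides or treatment
    if (r.tg is not None and r.tg >= 150.0) or r.on_tg_treatment:
        n += 1
    # 4. low HDL
    if r.hdl is not None and r.hdl < (40.0 if male else 50.0):
        n += 1
    # 5. impaired fasting glucose or HbA1c
    ifg = r.fbg is not None and 100.0 <= r.fbg <= 125.0
    if ifg or (r.hba1c is not None and r.hba1c >= 5.7):
        n += 1
    return n


def classify_eligibility(
    record: SubjectRecord, ast_alt_uln: float = DEFAULT_AST_ALT_ULN
) -> EligibilityLabel:
    """Screen a subject into MASLD / control / ineligible.

    Exclusion rules (toxic alcohol intake, transaminases > 5 × ULN) are
    evaluated first; every violated rule is recorded.  ``ast_alt_uln``
    is the upper normal limit used for the 5× transaminase exclusion.
    A CAP of exactly 248 dB/m satisfies neither the steatosis-evidence
    rule (>) nor the control rule (<), so such subjects fall through to
    ineligible.
    """
    r = record
    reasons: List[str] = []

    limit = 210.0 if r.sex == "male" else 140.0
    if r.alcohol_g_week is not None and r.alcohol_g_week > limit:
        reasons.append("alcohol_toxic_dose")
    if (r.ast is not None and r.ast > 5 * ast_alt_uln) or (
        r.alt is not None and r.alt > 5 * ast_alt_uln
    ):
        reasons.append("aminotransferases_gt_5x_uln")
    if reasons:
        return EligibilityLabel(label="ineligible", reasons=reasons)

    if r.cap is None and r.ultrasound_steatosis is None:
        return EligibilityLabel(
            label="ineligible", reasons=["no_steatosis_assessment"]
        )

    steatosis = bool(
        (r.cap is not None and r.cap > CAP_STEATOSIS_SCREEN)
        or r.ultrasound_steatosis
    )
    risk_factors = count_metabolic_risk_factors(r)
    diabetes = bool(r.diabetes_or_ifg)

    if steatosis:
        metabolic = (
            (r.bmi is not None and r.bmi >= 25.0)
            or diabetes
            or risk_factors >= 2
        )
        if metabolic:
            return EligibilityLabel(label="masld")
        return EligibilityLabel(
            label="ineligible", reasons=["steatosis_without_metabolic_dysfunction"]
        )

    # control requires absence confirmed by both modalities
    no_steatosis = (
        r.cap is not None
        and r.cap < CAP_STEATOSIS_SCREEN
        and r.ultrasound_steatosis is False
    )
    if no_steatosis and (r.bmi is not None and r.bmi < 25.0) and not diabetes \
            and risk_factors <= 1:
        return EligibilityLabel(label="control")

    why: List[str] = []
    if not no_steatosis:
        why.append("steatosis_absence_not_confirmed_by_both")
    if r.bmi is None or r.bmi >= 25.0:
        why.append("bmi_not_below_25")
    if diabetes:
        why.append("diabetes")
    if risk_factors > 1:
        why.append("more_than_one_risk_factor")
    return EligibilityLabel(label="ineligible", reasons=why)


def stage_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add steatosis/fibrosis grading columns to a cohort table.

    Returns a copy with ``steatosis_grade`` (S0–S3), ``steatosis_ordinal``,
    ``significant_steatosis``, ``fibrosis_stage`` (F0F1–F4),
    ``fibrosis_ordinal`` and ``severe_fibrosis`` columns.  Rows with
    missing CAP or stiffness get NaN / ordinal −1.
    """
    out = cohort.copy()

    def num(name: str) -> np.ndarray:
        if name not in out.columns:
            return np.full(len(out), np.nan)
        return pd.to_numeric(out[name], errors="coerce").to_numpy(float)

    cap = num("cap")
    te = num("te")

    s_ord = grade_steatosis_array(cap)
    f_ord = stage_fibrosis_array(te)
    out["steatosis_ordinal"] = s_ord
    out["steatosis_grade"] = [
        STEATOSIS_GRADES[i] if i >= 0 else None for i in s_ord
    ]
    out["significant_steatosis"] = np.where(s_ord >= 0, s_ord >= 2, None)
    out["fibrosis_ordinal"] = f_ord
    out["fibrosis_stage"] = [
        FIBROSIS_STAGES[i] if i >= 0 else None for i in f_ord
    ]
    out["severe_fibrosis"] = np.where(f_ord >= 0, f_ord >= 2, None)
    return out
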