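"""Metabolic and fibrosis index calculators.

Implements the five non-invasive scores used to assess hepatic steatosis
and fibrosis in metabolic dysfunction-associated steatotic liver disease
(MASLD):

* **TyG** — triglyceride–glucose index, ``log(FBG × TG / 2)``, an insulin
  resistance surrogate.  The log base is parameterised (see below).
* **VAI** — visceral adiposity index, a sex-specific composite of waist
  circumference, BMI, triglycerides and HDL cholesterol.
* **LAP** — lipid accumulation product, ``(WC − anchor) × TG`` with
  sex-specific waist anchors (65 cm men, 58 cm women).
* **NFS** — NAFLD fibrosis score, a linear score over age, BMI,
  dysglycemia, AST/ALT ratio, platelets and albumin.
* **FIB-4** — ``age × AST / (platelets × √ALT)``.

Units matter: labs are taken in the conventional mg/dL, U/L, g/dL and
10⁹/L units; VAI and LAP require triglycerides and HDL in mmol/L, so the
molar conversions are applied internally by :func:`compute_panel`.

The TyG log base deserves a note.  The defining formula uses the natural
logarithm, and that is the default here.  Published TyG values and
cut-offs, however, frequently sit on a scale (roughly 4–8) consistent
with a decimal logarithm; reported cut-offs vary widely for exactly this
reason.  Both conventions are exposed through ``log_base`` so a cohort
can be scored on either scale.  Rank-based statistics (Spearman
correlations, ROC curves) are identical under either choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "Sex",
    "LogBase",
    "SubjectRecord",
    "IndexPanel",
    "tg_mgdl_to_mmol",
    "hdl_mgdl_to_mmol",
    "compute_tyg",
    "compute_vai",
    "compute_lap",
    "compute_nfs",
    "compute_fib4",
    "compute_panel",
    "compute_panel_table",
]

Sex = Literal["male", "female"]
LogBase = Literal["natural", "decimal"]

#: mg/dL per mmol/L for triglycerides (MW ≈ 885.7 g/mol)
TG_MGDL_PER_MMOL = 88.57
#: mg/dL per mmol/L for cholesterol species (MW ≈ 386.7 g/mol)
HDL_MGDL_PER_MMOL = 38.67

# VAI anchor constants: WC/(a + b·BMI) · (TG/tg0) · (hdl0/HDL)
_VAI_PARAMS = {
    "male": (39.68, 1.88, 1.03, 1.31),
    "female": (36.58, 1.89, 0.81, 1.52),
}
# LAP waist anchors (cm)
_LAP_ANCHOR = {"male": 65.0, "female": 58.0}


class SubjectRecord(BaseModel):
    """One subject's demographics, anthropometrics, labs and elastography.

    All lab values use conventional units (mg/dL for lipids and glucose,
    U/L for transaminases, g/dL for albumin, 10⁹/L for platelets).  CAP is
    in dB/m and liver stiffness (``te``) in kPa, both restricted to the
    device measurement range.
    """

    subject_id: str
    sex: Sex
    age: float
    height: Optional[float] = None  # cm
    weight: Optional[float] = None  # kg
    bmi: Optional[float] = None  # kg/m²
    waist_circumference: Optional[float] = None  # cm
    fbg: Optional[float] = None  # mg/dL
    tg: Optional[float] = None  # mg/dL
    hdl: Optional[float] = None  # mg/dL
    ldl: Optional[float] = None  # mg/dL
    total_cholesterol: Optional[float] = None  # mg/dL
    ast: Optional[float] = None  # U/L
    alt: Optional[float] = None  # U/L
    ggt: Optional[float] = None  # U/L
    albumin: Optional[float] = None  # g/dL
    platelets: Optional[float] = None  # 10⁹/L
    diabetes_or_ifg: Optional[bool] = None
    on_antihypertensives: Optional[bool] = None
    systolic_bp: Optional[float] = None  # mmHg
    diastolic_bp: Optional[float] = None  # mmHg
    on_tg_treatment: Optional[bool] = None
    hba1c: Optional[float] = None  # %
    alcohol_g_week: Optional[float] = None  # g/week
    cap: Optional[float] = None  # dB/m
    te: Optional[float] = None  # kPa
    te_iqr_over_median: Optional[float] = None
    te_valid_count: Optional[int] = None
    ultrasound_steatosis: Optional[bool] = None

    model_config = {"extra": "allow"}

    @model_validator(mode="after")
    def _check_physiology(self) -> "SubjectRecord":
        strictly_positive = (
            "age", "height", "weight", "bmi", "waist_circumference", "fbg",
            "tg", "hdl", "ldl", "total_cholesterol", "ast", "alt", "ggt",
            "albumin", "platelets", "hba1c",
        )
        for name in strictly_positive:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.alcohol_g_week is not None and self.alcohol_g_week < 0:
            raise ValueError("alcohol_g_week must be non-negative")
        if self.te_iqr_over_median is not None and self.te_iqr_over_median < 0:
            raise ValueError("te_iqr_over_median must be non-negative")
        if self.te is not None and not (2.5 <= self.te <= 75.0):
            raise ValueError(f"te outside device range [2.5, 75] kPa: {self.te}")
        if self.cap is not None and not (100.0 <= self.cap <= 400.0):
            raise ValueError(f"cap outside device range [100, 400] dB/m: {self.cap}")
        if self.bmi is not None and self.height and self.weight:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.1:
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with height/weight "
                    f"(implied {implied:.2f})"
                )
        if self.bmi is None and self.height and self.weight:
            object.__setattr__(
                self, "bmi", self.weight / (self.height / 100.0) ** 2
            )
        return self


@dataclass(frozen=True)
class IndexPanel:
    """The five computed scores for one subject.

    Any score whose inputs are incomplete is ``None`` — never a silent
    zero.  ``tyg_log_base`` records the log convention used for TyG.
    """

    tyg: Optional[float]
    vai: Optional[float]
    lap: Optional[float]  # cm·mmol/L
    nfs: Optional[float]
    fib4: Optional[float]
    tyg_log_base: LogBase = "natural"


def tg_mgdl_to_mmol(tg: float) -> float:
    """Convert triglycerides from mg/dL to mmol/L."""
    if tg < 0:
        raise ValueError(f"triglycerides must be non-negative, got {tg}")
    return tg / TG_MGDL_PER_MMOL


def hdl_mgdl_to_mmol(hdl: float) -> float:
    """Convert HDL cholesterol from mg/dL to mmol/L."""
    if hdl < 0:
        raise ValueError(f"HDL must be non-negative, got {hdl}")
    return hdl / HDL_MGDL_PER_MMOL


def compute_tyg(fbg: float, tg: float, log_base: LogBase = "natural") -> float:
    """Triglyceride–glucose index: log(FBG[mg/dL] × TG[mg/dL] / 2).

    Parameters
    ----------
    fbg, tg
        Fasting blood glucose and triglycerides, both mg/dL, both > 0.
    log_base
        ``"natural"`` (the defining formula) or ``"decimal"``.
    """
    if fbg <= 0 or tg <= 0:
        raise ValueError("fbg and tg must be strictly positive")
    x = fbg * tg / 2.0
    if log_base == "natural":
        return math.log(x)
    if log_base == "decimal":
        return math.log10(x)
    raise ValueError(f"unknown log base: {log_base!r}")


def compute_vai(sex: Sex, wc: float, bmi: float, tg: float, hdl: float) -> float:
    """Visceral adiposity index (sex-specific).

    ``tg`` and ``hdl`` must already be in mmol/L.  At the anchor values
    (e.g. male: WC = 39.68 + 1.88·BMI, TG = 1.03, HDL = 1.31) VAI is
    exactly 1, representing a metabolically healthy reference subject.
    """
    if sex not in _VAI_PARAMS:
        raise ValueError(f"unknown sex: {sex!r}")
    if wc <= 0 or bmi <= 0 or tg <= 0 or hdl <= 0:
        raise ValueError("wc, bmi, tg and hdl must be strictly positive")
    a, b, tg0, hdl0 = _VAI_PARAMS[sex]
    return wc / (a + b * bmi) * (tg / tg0) * (hdl0 / hdl)


def compute_lap(sex: Sex, wc: float, tg: float) -> float:
    """Lipid accumulation product, (WC − anchor) × TG[mmol/L].

    Negative values are possible when the waist circumference is below
    the sex anchor (65 cm men / 58 cm women); they are returned as-is.
    """
    if sex not in _LAP_ANCHOR:
        raise ValueError(f"unknown sex: {sex!r}")
    if wc <= 0 or tg <= 0:
        raise ValueError("wc and tg must be strictly positive")
    return (wc - _LAP_ANCHOR[sex]) * tg


def compute_nfs(
    age: float,
    bmi: float,
    diabetes_or_ifg: bool,
    ast: float,
    alt: float,
    platelets: float,
    albumin: float,
) -> float:
    """NAFLD fibrosis score.

    −1.675 + 0.037·age + 0.094·BMI + 1.13·dysglycemia + 0.99·AST/ALT
    − 0.013·platelets(10⁹/L) − 0.66·albumin(g/dL).
    """
    if alt <= 0:
        raise ValueError("alt must be strictly positive (AST/ALT undefined)")
    if min(age, bmi, ast, platelets, albumin) <= 0:
        raise ValueError("all quantities must be strictly positive")
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * (1.0 if diabetes_or_ifg else 0.0)
        + 0.99 * (ast / alt)
        - 0.013 * platelets
        - 0.66 * albumin
    )


def compute_fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """FIB-4 index: age × AST / (platelets × √ALT)."""
    if min(age, ast, alt, platelets) <= 0:
        raise ValueError("all inputs must be strictly positive")
    return age * ast / (platelets * math.sqrt(alt))


def compute_panel(record: SubjectRecord, tyg_log_base: LogBase = "natural") -> IndexPanel:
    """Compute every index whose inputs are present on ``record``.

    Missing inputs make the corresponding index ``None``; no imputation
    is performed.
    """
    tyg = vai = lap = nfs = fib4 = None
    r = record
    if r.fbg is not None and r.tg is not None:
        tyg = compute_tyg(r.fbg, r.tg, tyg_log_base)
    if (
        r.waist_circumference is not None
        and r.bmi is not None
        and r.tg is not None
        and r.hdl is not None
    ):
        vai = compute_vai(
            r.sex,
            r.waist_circumference,
            r.bmi,
            tg_mgdl_to_mmol(r.tg),
            hdl_mgdl_to_mmol(r.hdl),
        )
    if r.waist_circumference is not None and r.tg is not None:
        lap = compute_lap(r.sex, r.waist_circumference, tg_mgdl_to_mmol(r.tg))
    if (
        r.bmi is not None
        and r.diabetes_or_ifg is not None
        and r.ast is not None
        and r.alt is not None
        and r.platelets is not None
        and r.albumin is not None
    ):
        nfs = compute_nfs(
            r.age, r.bmi, r.diabetes_or_ifg, r.ast, r.alt, r.platelets, r.albumin
        )
    if r.ast is not None and r.alt is not None and r.platelets is not None:
        fib4 = compute_fib4(r.age, r.ast, r.alt, r.platelets)
    return IndexPanel(tyg=tyg, vai=vai, lap=lap, nfs=nfs, fib4=fib4,
                      tyg_log_base=tyg_log_base)


def compute_panel_table(
    cohort: pd.DataFrame, tyg_log_base: LogBase = "natural"
) -> pd.DataFrame:
    """Vectorised :func:`compute_panel` over a cohort table.

    Expects the :class:`SubjectRecord` column names; returns a frame
    indexed like ``cohort`` with columns ``tyg, vai, lap, nfs, fib4``
    (NaN where inputs are missing).
    """
    c = cohort
    out = pd.DataFrame(index=c.index)

    def num(name: str) -> np.ndarray:
        if name not in c.columns:
            return np.full(len(c), np.nan)
        return pd.to_numeric(c[name], errors="coerce").to_numpy(float)

    fbg, tg = num("fbg"), num("tg")
    logf = np.log if tyg_log_base == "natural" else np.log10
    if tyg_log_base not in ("natural", "decimal"):
        raise ValueError(f"unknown log base: {tyg_log_base!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["tyg"] = logf(fbg * tg / 2.0)

    tg_mmol = tg / TG_MGDL_PER_MMOL
    hdl_mmol = num("hdl") / HDL_MGDL_PER_MMOL
    wc = num("waist_circumference")
    bmi = num("bmi")
    male = (c["sex"] == "male").to_numpy()
    a = np.where(male, 39.68, 36.58)
    b = np.where(male, 1.88, 1.89)
    tg0 = np.where(male, 1.03, 0.81)
    hdl0 = np.where(male, 1.31, 1.52)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["vai"] = wc / (a + b * bmi) * (tg_mmol / tg0) * (hdl0 / hdl_mmol)
    out["lap"] = (wc - np.where(male, 65.0, 58.0)) * tg_mmol

    if "diabetes_or_ifg" in c.columns:
        dia = c["diabetes_or_ifg"].map(
            {True: 1.0, False: 0.0, 1: 1.0, 0: 0.0}
        ).to_numpy(float)
    else:
        dia = np.full(len(c), np.nan)
    age, ast, alt = num("age"), num("ast"), num("alt")
    plt_, alb = num("platelets"), num("albumin")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["nfs"] = (
            -1.675 + 0.037 * age + 0.094 * bmi
            + 1.13 * dia + 0.99 * (ast / alt) - 0.013 * plt_ - 0.66 * alb
        )
        out["fib4"] = age * ast / (plt_ * np.sqrt(alt))
    return out
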