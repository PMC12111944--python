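"""Two-stage sequential classification of severe fibrosis (F3–F4).

Stage 1 applies the published NFS and FIB-4 rule-in / rule-out
cut-offs jointly:

* ruled out:  NFS ≤ −1.455  AND  FIB-4 ≤ 1.3
* ruled in:   NFS >  0.676  AND  FIB-4 > 2.67
* otherwise the subject sits in the grey zone.

Stage 2 re-examines only grey-zone subjects using rule-in / rule-out
cut-offs for the metabolic indices TyG and VAI (defaults derived on the
study scale: rule-in TyG > 5.61 and VAI > 6.21; rule-out TyG ≤ 2.65 and
VAI ≤ 1.67).  By default both indices must agree (``combination="both"``,
mirroring the AND logic of stage 1); an ``"either"`` mode accepts a
single decisive index, with discordant signals always left unclassified.

Correctness is assessed against transient-elastography staging: a
correct rule-out has a non-severe reference stage (F0–F2), a correct
rule-in a severe one (F3–F4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence

import math

import numpy as np
import pandas as pd

__all__ = [
    "ScoreCutoffs",
    "CascadeCutoffs",
    "CascadeResult",
    "ClassificationReport",
    "DEFAULT_CASCADE_CUTOFFS",
    "stage1_classify",
    "stage2_classify",
    "run_cascade",
    "evaluate_cascade",
]

Combination = Literal["both", "either"]


@dataclass(frozen=True)
class ScoreCutoffs:
    """Rule-in / rule-out thresholds for one score.

    ``rule_out`` and ``rule_in`` bound the grey zone; whenever both and
    an optimal threshold are present they must be ordered
    rule_out ≤ optimal ≤ rule_in.
    """

    score_name: str
    rule_out: float
    rule_in: float
    optimal: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = self.rule_out, self.rule_in
        if lo > hi:
            raise ValueError(
                f"{self.score_name}: rule_out {lo} exceeds rule_in {hi}"
            )
        if self.optimal is not None and not (lo <= self.optimal <= hi):
            raise ValueError(
                f"{self.score_name}: optimal {self.optimal} outside "
                f"[rule_out, rule_in] = [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class CascadeCutoffs:
    """The four cut-off sets driving the two cascade stages."""

    nfs: ScoreCutoffs
    fib4: ScoreCutoffs
    tyg: ScoreCutoffs
    vai: ScoreCutoffs
    combination: Combination = "both"


def _cutoffs_from_defaults() -> "CascadeCutoffs":
    from ._defaults import DEFAULTS

    cfg = DEFAULTS["cascade"]

    def mk(name: str) -> ScoreCutoffs:
        d = cfg[name]
        return ScoreCutoffs(
            name,
            rule_out=float(d["rule_out"]),
            rule_in=float(d["rule_in"]),
            optimal=float(d["optimal"]) if "optimal" in d else None,
        )

    return CascadeCutoffs(
        nfs=mk("nfs"), fib4=mk("fib4"), tyg=mk("tyg"), vai=mk("vai"),
        combination=cfg.get("combination", "both"),
    )


#: Published NFS/FIB-4 cut-offs and study-scale TyG/VAI cut-offs.
DEFAULT_CASCADE_CUTOFFS = _cutoffs_from_defaults()


@dataclass(frozen=True)
class CascadeResult:
    subject_id: str
    label: Literal["ruled_out", "ruled_in", "unclassified"]
    stage: Literal[1, 2, 0]  # 0 = never classified
    inputs_used: Sequence[str] = ()
    reason: Optional[str] = None


def _is_missing(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def stage1_classify(
    nfs: Optional[float],
    fib4: Optional[float],
    cutoffs: CascadeCutoffs = DEFAULT_CASCADE_CUTOFFS,
) -> str:
    """Stage-1 label from NFS and FIB-4: ruled_out / ruled_in / grey.

    A missing score cannot support either joint rule, so the subject is
    grey.
    """
    if _is_missing(nfs) or _is_missing(fib4):
        return "grey"
    if nfs <= cutoffs.nfs.rule_out and fib4 <= cutoffs.fib4.rule_out:
        return "ruled_out"
    if nfs > cutoffs.nfs.rule_in and fib4 > cutoffs.fib4.rule_in:
        return "ruled_in"
    return "grey"


def stage2_classify(
    tyg: Optional[float],
    vai: Optional[float],
    cutoffs: CascadeCutoffs = DEFAULT_CASCADE_CUTOFFS,
) -> str:
    """Stage-2 label from TyG and VAI for a stage-1 grey subject.

    Under ``combination="both"`` the two indices must agree on the same
    side; under ``"either"`` one decisive index suffices unless the other
    points the opposite way (a conflict), which is never resolved.
    """
    if _is_missing(tyg) or _is_missing(vai):
        return "unclassified"
    in_votes = (tyg > cutoffs.tyg.rule_in, vai > cutoffs.vai.rule_in)
    out_votes = (tyg <= cutoffs.tyg.rule_out, vai <= cutoffs.vai.rule_out)
    if any(in_votes) and any(out_votes):
        return "conflict"
    if cutoffs.combination == "both":
        if all(in_votes):
            return "ruled_in"
        if all(out_votes):
            return "ruled_out"
    elif cutoffs.combination == "either":
        if any(in_votes):
            return "ruled_in"
        if any(out_votes):
            return "ruled_out"
    else:
        raise ValueError(f"unknown combination rule: {cutoffs.combination!r}")
    return "unclassified"


def run_cascade(
    panels: pd.DataFrame,
    cutoffs: CascadeCutoffs = DEFAULT_CASCADE_CUTOFFS,
) -> pd.DataFrame:
    """Run the two-stage cascade over a panel table.

    ``panels`` must contain ``nfs``, ``fib4``, ``tyg``, ``vai`` columns
    and either a ``subject_id`` column or a meaningful index.  Returns
    one row per subject with columns ``subject_id, label, stage,
    inputs_used, reason``.  Stage 2 is applied only to stage-1 grey
    subjects; classified subjects are never relabelled.
    """
    if len(panels) == 0:
        return pd.DataFrame(
            columns=["subject_id", "label", "stage", "inputs_used", "reason"]
        )
    ids = (
        panels["subject_id"].astype(str)
        if "subject_id" in panels.columns
        else panels.index.astype(str)
    )
    rows: List[dict] = []
    for sid, nfs, fib4, tyg, vai in zip(
        ids,
        panels.get("nfs", pd.Series(np.nan, index=panels.index)),
        panels.get("fib4", pd.Series(np.nan, index=panels.index)),
        panels.get("tyg", pd.Series(np.nan, index=panels.index)),
        panels.get("vai", pd.Series(np.nan, index=panels.index)),
    ):
        s1 = stage1_classify(nfs, fib4, cutoffs)
        if s1 != "grey":
            rows.append(
                dict(subject_id=sid, label=s1, stage=1,
                     inputs_used="nfs,fib4", reason=None)
            )
            continue
        s2 = stage2_classify(tyg, vai, cutoffs)
        if s2 in ("ruled_out", "ruled_in"):
            rows.append(
                dict(subject_id=sid, label=s2, stage=2,
                     inputs_used="tyg,vai", reason=None)
            )
        else:
            rows.append(
                dict(
                    subject_id=sid,
                    label="unclassified",
                    stage=0,
                    inputs_used="nfs,fib4,tyg,vai",
                    reason="conflict" if s2 == "conflict" else None,
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassificationReport:
    """Cascade counts and correctness against the elastography reference."""

    n_total: int
    n_stage1_ruled_out: int
    n_stage1_ruled_in: int
    n_grey: int
    n_stage2_ruled_out: int
    n_stage2_ruled_in: int
    n_stage1_ruled_out_correct: int
    n_stage1_ruled_in_correct: int
    n_stage2_correct: int
    pct_unclassified_before: float
    pct_unclassified_after: float

    @property
    def n_stage2_classified(self) -> int:
        return self.n_stage2_ruled_out + self.n_stage2_ruled_in

    @property
    def n_unclassified_after(self) -> int:
        return self.n_grey - self.n_stage2_classified

    def __post_init__(self) -> None:
        if (
            self.n_stage1_ruled_out + self.n_stage1_ruled_in + self.n_grey
            != self.n_total
        ):
            raise ValueError("stage-1 counts do not partition the cohort")
        if self.n_stage2_classified > self.n_grey:
            raise ValueError("stage 2 classified more subjects than were grey")
        if self.pct_unclassified_after > self.pct_unclassified_before + 1e-12:
            raise ValueError("cascade increased the unclassified fraction")


def evaluate_cascade(
    results: pd.DataFrame, reference: pd.DataFrame
) -> ClassificationReport:
    """Score cascade results against TE-based fibrosis staging.

    ``reference`` needs ``subject_id`` and ``severe_fibrosis`` (boolean)
    columns.  Every classified subject must have a reference stage; a
    correct rule-out has a non-severe reference, a correct rule-in a
    severe one.  Percentages are on the full cohort denominator.
    """
    if len(results) == 0:
        return ClassificationReport(0, 0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0)
    ref = reference.set_index(reference["subject_id"].astype(str))[
        "severe_fibrosis"
    ]
    classified = results[results["label"] != "unclassified"]
    missing = set(classified["subject_id"].astype(str)) - set(ref.index)
    if missing:
        raise KeyError(
            f"classified subjects missing from reference: {sorted(missing)}"
        )

    n_total = len(results)
    severe = results["subject_id"].astype(str).map(ref)

    s1 = results["stage"] == 1
    s2 = results["stage"] == 2
    out1 = s1 & (results["label"] == "ruled_out")
    in1 = s1 & (results["label"] == "ruled_in")
    out2 = s2 & (results["label"] == "ruled_out")
    in2 = s2 & (results["label"] == "ruled_in")

    n_grey = int(n_total - out1.sum() - in1.sum())
    n_s2_class = int(out2.sum() + in2.sum())
    return ClassificationReport(
        n_total=n_total,
        n_stage1_ruled_out=int(out1.sum()),
        n_stage1_ruled_in=int(in1.sum()),
        n_grey=n_grey,
        n_stage2_ruled_out=int(out2.sum()),
        n_stage2_ruled_in=int(in2.sum()),
        n_stage1_ruled_out_correct=int((out1 & (severe == False)).sum()),  # noqa: E712
        n_stage1_ruled_in_correct=int((in1 & (severe == True)).sum()),  # noqa: E712
        n_stage2_correct=int(
            (out2 & (severe == False)).sum() + (in2 & (severe == True)).sum()  # noqa: E712
        ),
        pct_unclassified_before=100.0 * n_grey / n_total,
        pct_unclassified_after=100.0 * (n_grey - n_s2_class) / n_total,
    )
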