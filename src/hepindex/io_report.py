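"""Cohort table I/O, run configuration and report rendering.

Cohorts travel as comma-delimited text with a header row; the column
dictionary is the :class:`~hepindex.indices.SubjectRecord` field list.
Loading validates each row against the record model, collects failures
with their file line numbers, and passes valid rows through — a partial
load is an explicit, inspectable outcome, not an error.

Reports mirror the layout clinicians expect from a grey-zone cascade
evaluation: a rule-out / grey / rule-in margin with per-cell
correctness against the elastography reference, plus the headline
reduction in unclassified subjects.  Percentages are rendered to one
decimal, rounding half-up.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError

from . import __version__
from ._defaults import DEFAULTS
from .cascade import ClassificationReport
from .indices import SubjectRecord

__all__ = [
    "CohortLoadResult",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "round_pct",
    "render_report",
]

MANDATORY_COLUMNS = ("subject_id", "sex", "age")

_RECORD_FIELDS = list(SubjectRecord.model_fields)
_BOOL_FIELDS = [
    "diabetes_or_ifg", "on_antihypertensives", "on_tg_treatment",
    "ultrasound_steatosis",
]


@dataclass
class CohortLoadResult:
    """Outcome of reading a cohort file.

    ``records`` holds the valid rows; ``errors`` is a list of
    ``(line_number, message)`` for rejected rows.  ``partial`` is true
    when at least one row was rejected.
    """

    records: pd.DataFrame
    errors: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def partial(self) -> bool:
        return len(self.errors) > 0


def _parse_bool(x):
    if isinstance(x, str):
        s = x.strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        if s == "":
            return None
        raise ValueError(f"not a boolean: {x!r}")
    return x


def read_cohort(path: str | Path) -> CohortLoadResult:
    """Read and validate a comma-delimited cohort table.

    Missing mandatory columns raise immediately, naming them.  Rows that
    fail physiologic validation are collected (with their 1-based file
    line numbers, header = line 1) and excluded from ``records``.
    Unknown columns are preserved untouched.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    known = [c for c in raw.columns if c in _RECORD_FIELDS]
    extra = [c for c in raw.columns if c not in _RECORD_FIELDS]

    rows: List[dict] = []
    keep_idx: List[int] = []
    errors: List[Tuple[int, str]] = []
    for i, row in raw.iterrows():
        payload = {}
        try:
            for c in known:
                v = row[c]
                if isinstance(v, str) and v.strip() == "":
                    continue
                payload[c] = _parse_bool(v) if c in _BOOL_FIELDS else v
            rec = SubjectRecord(**payload)
        except (ValidationError, ValueError) as exc:
            errors.append((int(i) + 2, _short_error(exc)))
            continue
        d = rec.model_dump()
        for c in extra:
            d[c] = row[c]
        rows.append(d)
        keep_idx.append(int(i))

    cols = _RECORD_FIELDS + extra
    records = pd.DataFrame(rows, columns=cols if rows else cols)
    records = records.dropna(axis=1, how="all")
    return CohortLoadResult(records=records, errors=errors)


def _short_error(exc: Exception) -> str:
    if isinstance(exc, ValidationError):
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first.get("loc", ()))
        return f"{loc}: {first.get('msg', 'invalid')}"
    return str(exc)


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as comma-delimited text."""
    records.to_csv(path, index=False)


class RunConfig(BaseModel):
    """Runtime configuration; every constant defaults to the shipped
    defaults file and any override is recorded in ``overrides``."""

    tyg_log_base: Literal["natural", "decimal"] = DEFAULTS["indices"]["tyg_log_base"]
    cascade_combination: Literal["both", "either"] = DEFAULTS["cascade"]["combination"]
    rule_out_se_floor: float = DEFAULTS["diagnostics"]["rule_out_se_floor"]
    rule_in_sp_floor: float = DEFAULTS["diagnostics"]["rule_in_sp_floor"]
    cascade_cutoffs: Dict[str, Dict[str, float]] = {
        k: dict(v) for k, v in DEFAULTS["cascade"].items() if isinstance(v, dict)
    }
    seed: int = 0
    overrides: List[str] = []

    @classmethod
    def from_yaml(cls, path: Optional[str | Path] = None, **kwargs) -> "RunConfig":
        data = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(kwargs)
        defaults = cls()
        overrides = [
            f"{k}={v!r}" for k, v in data.items()
            if k in cls.model_fields and getattr(defaults, k) != v
        ]
        cfg = cls(**data)
        cfg.overrides = overrides
        return cfg

    def provenance(self) -> Dict[str, object]:
        """Config hash + seed + version: enough to reproduce a run."""
        payload = self.model_dump(exclude={"overrides"})
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return {
            "config_sha256": digest,
            "seed": self.seed,
            "hepindex_version": __version__,
            "overrides": list(self.overrides),
        }


def round_pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places; NaN if the
    denominator is zero."""
    if denominator == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def render_report(
    report: ClassificationReport,
    performances: Optional[Dict[str, dict]] = None,
    correlations: Optional[Dict[str, dict]] = None,
    provenance: Optional[Dict[str, object]] = None,
) -> Tuple[Dict[str, object], str]:
    """Render a cascade evaluation as (JSON-ready dict, Markdown).

    The table mirrors the rule-out / grey-zone / rule-in margin with
    correctness against the elastography reference; the headline is the
    drop in unclassified subjects after the second stage.
    """
    r = report
    n = r.n_total
    empty = n == 0

    cells = {
        "n_total": n,
        "stage1": {
            "ruled_out": {
                "n": r.n_stage1_ruled_out,
                "pct": round_pct(r.n_stage1_ruled_out, n) if not empty else 0.0,
                "correct": r.n_stage1_ruled_out_correct,
                "pct_correct": round_pct(
                    r.n_stage1_ruled_out_correct, r.n_stage1_ruled_out
                ),
            },
            "grey": {
                "n": r.n_grey,
                "pct": round_pct(r.n_grey, n) if not empty else 0.0,
            },
            "ruled_in": {
                "n": r.n_stage1_ruled_in,
                "pct": round_pct(r.n_stage1_ruled_in, n) if not empty else 0.0,
                "correct": r.n_stage1_ruled_in_correct,
                "pct_correct": round_pct(
                    r.n_stage1_ruled_in_correct, r.n_stage1_ruled_in
                ),
            },
        },
        "stage2": {
            "classified": r.n_stage2_classified,
            "pct_of_grey": round_pct(r.n_stage2_classified, r.n_grey),
            "correct": r.n_stage2_correct,
            "pct_correct": round_pct(r.n_stage2_correct, r.n_stage2_classified),
        },
        "unclassified": {
            "before_pct": round_pct(r.n_grey, n) if not empty else 0.0,
            "after_pct": round_pct(r.n_unclassified_after, n) if not empty else 0.0,
        },
    }
    doc: Dict[str, object] = {"cascade": cells}
    if performances:
        doc["performances"] = performances
    if correlations:
        doc["correlations"] = correlations
    if provenance:
        doc["provenance"] = provenance

    s1, s2, u = cells["stage1"], cells["stage2"], cells["unclassified"]
    lines = [
        "# Severe-fibrosis cascade classification",
        "",
    ]
    if empty:
        lines.append("**Empty cohort: n = 0 — no classification performed.**")
    lines += [
        f"Subjects evaluated: **{n}**",
        "",
        "| | Absence of F3–F4 | Unclassified subjects | Presence of F3–F4 |",
        "|---|---|---|---|",
        (
            "| Stage 1 (NFS + FIB-4) | "
            f"{s1['ruled_out']['n']}/{n} ({s1['ruled_out']['pct']}%) | "
            f"{s1['grey']['n']}/{n} ({s1['grey']['pct']}%) | "
            f"{s1['ruled_in']['n']}/{n} ({s1['ruled_in']['pct']}%) |"
        ),
        (
            "| Correct vs elastography | "
            f"{s1['ruled_out']['correct']}/{s1['ruled_out']['n']} "
            f"({s1['ruled_out']['pct_correct']}%) | — | "
            f"{s1['ruled_in']['correct']}/{s1['ruled_in']['n']} "
            f"({s1['ruled_in']['pct_correct']}%) |"
        ),
        (
            "| Stage 2 (TyG + VAI) | — | "
            f"{s2['classified']}/{s1['grey']['n']} ({s2['pct_of_grey']}%) "
            f"additionally classified, {s2['correct']}/{s2['classified']} "
            f"({s2['pct_correct']}%) correct | — |"
        ),
        "",
        (
            f"**Unclassified subjects: {u['before_pct']}% → "
            f"{u['after_pct']}% after the second stage.**"
        ),
    ]
    return doc, "\n".join(lines)
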