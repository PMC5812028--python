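"""Domain types for pediatric EHR corpora and gold-standard labels.

A corpus is a JSON-Lines file with one patient object per line (see
``docs/corpus_schema.md``).  Dates are ISO-8601 strings on disk and
:class:`datetime.date` in memory.  Character offsets anywhere in this
package are 0-based half-open over the raw note text.
"""

from __future__ import annotations

import csv
import json
import warnings
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Any, Optional, Union

from pydantic import BaseModel, Field, field_validator

__all__ = [
    "Sex",
    "Race",
    "Analyte",
    "PPIField",
    "YesNoUnknown",
    "ClinicalNote",
    "LabResult",
    "PPIRecord",
    "PatientRecord",
    "GoldLabel",
    "ValidationIssue",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "read_gold",
    "write_gold",
    "validate_record",
]


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class Race(str, Enum):
    white = "white"
    nonwhite = "nonwhite"
    unknown = "unknown"


class Analyte(str, Enum):
    eosinophil_pct = "eosinophil_pct"
    eosinophil_abs = "eosinophil_abs"
    other = "other"


class PPIField(str, Enum):
    mother_asthma = "mother_asthma"
    father_asthma = "father_asthma"


class YesNoUnknown(str, Enum):
    yes = "yes"
    no = "no"
    unknown = "unknown"


class ClinicalNote(BaseModel):
    """A dated free-text clinical note."""

    note_id: str
    date: date
    text: str

    @field_validator("text")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("note text must be non-empty")
        return v


class LabResult(BaseModel):
    """A laboratory result; eosinophil percentages drive the API minor criterion."""

    date: date
    analyte: Analyte
    value: float = Field(ge=0)
    units: str = ""


class PPIRecord(BaseModel):
    """Patient-provided information: a structured questionnaire answer."""

    date: date
    field: PPIField
    value: YesNoUnknown


class PatientRecord(BaseModel):
    """One child's EHR extract: notes, labs, questionnaire answers, covariates."""

    patient_id: str
    sex: Sex = Sex.unknown
    race: Race = Race.unknown
    gestational_age_weeks: Optional[float] = None
    birth_date: date
    notes: list[ClinicalNote] = Field(default_factory=list)
    labs: list[LabResult] = Field(default_factory=list)
    ppi: list[PPIRecord] = Field(default_factory=list)
    covariates: dict[str, Union[float, int, bool, None]] = Field(default_factory=dict)
    extras: dict[str, Any] = Field(default_factory=dict)

    def sorted_copy(self) -> "PatientRecord":
        """Return a copy with notes/labs/ppi sorted by date (stable)."""
        rec = self.model_copy(deep=True)
        rec.notes.sort(key=lambda n: (n.date, n.note_id))
        rec.labs.sort(key=lambda l: l.date)
        rec.ppi.sort(key=lambda p: p.date)
        return rec


class GoldLabel(BaseModel):
    """Reference-standard asthma status from manual chart review."""

    patient_id: str
    status: str  # "positive" | "negative"
    index_date: Optional[date] = None

    @field_validator("status")
    @classmethod
    def _status_enum(cls, v: str) -> str:
        if v not in ("positive", "negative"):
            raise ValueError(f"status must be positive/negative, got {v!r}")
        return v


class ValidationIssue(BaseModel):
    """A single invariant violation found in a record (reported, never raised)."""

    patient_id: str
    severity: str  # "error" | "warning"
    field: str
    message: str


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the documented JSON-Lines dialect."""


# ---------------------------------------------------------------------------
# Readers / writers


def read_corpus(path: Union[str, Path]) -> list[PatientRecord]:
    """Read a JSON-Lines corpus (one patient object per line).

    Notes and labs are returned date-sorted.  A malformed line raises
    :class:`CorpusFormatError` naming its 1-based line number; duplicate
    patient ids raise; a note/lab/ppi dated before birth only warns and
    the record is kept.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc})") from exc
            if not isinstance(obj, dict) or "patient_id" not in obj:
                raise CorpusFormatError(f"line {lineno}: missing patient_id")
            # forward compatibility: unknown top-level keys ride in extras
            unknown = set(obj) - set(PatientRecord.model_fields)
            if unknown:
                extras = dict(obj.get("extras") or {})
                extras.update({k: obj.pop(k) for k in sorted(unknown)})
                obj["extras"] = extras
            try:
                rec = PatientRecord.model_validate(obj)
            except Exception as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
            if rec.patient_id in seen:
                raise CorpusFormatError(
                    f"line {lineno}: duplicate patient_id {rec.patient_id!r}"
                )
            seen.add(rec.patient_id)
            rec = rec.sorted_copy()
            for issue in validate_record(rec):
                if issue.severity == "warning":
                    warnings.warn(f"{rec.patient_id}: {issue.message}", stacklevel=2)
            records.append(rec)
    return records


def write_corpus(records: list[PatientRecord], path: Union[str, Path]) -> None:
    """Write patients as JSON Lines; inverse of :func:`read_corpus`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.model_dump_json() + "\n")


def read_gold(path: Union[str, Path]) -> list[GoldLabel]:
    """Read a gold-label CSV with columns patient_id,status,index_date."""
    labels: list[GoldLabel] = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            idx = row.get("index_date") or None
            labels.append(
                GoldLabel(
                    patient_id=row["patient_id"],
                    status=row["status"],
                    index_date=idx,
                )
            )
    return labels


def write_gold(labels: list[GoldLabel], path: Union[str, Path]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "status", "index_date"])
        for lab in labels:
            writer.writerow(
                [
                    lab.patient_id,
                    lab.status,
                    lab.index_date.isoformat() if lab.index_date else "",
                ]
            )


# ---------------------------------------------------------------------------
# Validation


def validate_record(record: PatientRecord) -> list[ValidationIssue]:
    """Check record invariants; returns a deterministic list of issues.

    Never raises: problems are reported so callers can decide policy.
    """
    issues: list[ValidationIssue] = []

    def add(severity: str, field: str, message: str) -> None:
        issues.append(
            ValidationIssue(
                patient_id=record.patient_id,
                severity=severity,
                field=field,
                message=message,
            )
        )

    for note in record.notes:
        if note.date < record.birth_date:
            add("warning", "notes", f"note {note.note_id} dated before birth")
    for lab in record.labs:
        if lab.date < record.birth_date:
            add("warning", "labs", f"lab on {lab.date} dated before birth")
        if lab.analyte is Analyte.eosinophil_pct and not (0 <= lab.value <= 100):
            add(
                "error",
                "labs",
                f"eosinophil_pct value {lab.value} outside [0, 100]",
            )
    for ppi in record.ppi:
        if ppi.date < record.birth_date:
            add("warning", "ppi", f"ppi on {ppi.date} dated before birth")
    seen_ppi: set[tuple] = set()
    for ppi in record.ppi:
        key = (ppi.field, ppi.date)
        if key in seen_ppi:
            add("error", "ppi", f"conflicting PPI values for {key}")
        seen_ppi.add(key)
    return issues
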