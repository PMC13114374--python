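"""Patient records, validation, and delimited-table input/output.

One row per patient. Units are fixed by contract: creatinine in mg/dL,
glucose and triglycerides in mg/dL (fasting), UACR in mg/g, age in years.
Missing laboratory values are represented as ``None`` in records and as
empty cells in tables — never as zeros or numeric sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "CompleteCaseReport",
    "TableDialect",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
]


class CohortError(ValueError):
    """Malformed cohort table or invalid patient record."""


# canonical column order used by read/write
_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "creatinine",
    "glucose",
    "triglycerides",
    "uacr",
    "n_medications",
    "diagnosis_text",
    "medication_text",
    "dialysis_flag",
)

_NUMERIC_FIELDS = ("age", "creatinine", "glucose", "triglycerides", "uacr")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, labs and free-text fields.

    Lab fields may be ``None`` (missing). All present lab values must be
    strictly positive except ``uacr``, which may be 0.
    """

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    creatinine: float | None = None
    glucose: float | None = None
    triglycerides: float | None = None
    uacr: float | None = None
    n_medications: int | None = None
    diagnosis_text: str = ""
    medication_text: str = ""
    dialysis_flag: bool = False

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortError("patient_id must be a non-empty string")
        if self.sex not in ("female", "male"):
            raise CohortError(
                f"patient {self.patient_id!r}: sex must be 'female' or 'male', got {self.sex!r}"
            )
        if not (0 < self.age <= 130):
            raise CohortError(f"patient {self.patient_id!r}: age {self.age} outside (0, 130]")
        for name in ("creatinine", "glucose", "triglycerides"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise CohortError(
                    f"patient {self.patient_id!r}: {name} must be > 0, got {value}"
                )
        if self.uacr is not None and self.uacr < 0:
            raise CohortError(f"patient {self.patient_id!r}: uacr must be >= 0")
        if self.n_medications is not None and self.n_medications < 0:
            raise CohortError(f"patient {self.patient_id!r}: n_medications must be >= 0")

    def missing_fields(self) -> list[str]:
        """Fields required for full index computation that are absent here."""
        missing = [
            name
            for name in ("glucose", "triglycerides", "creatinine")
            if getattr(self, name) is None
        ]
        if not self.diagnosis_text.strip():
            missing.append("diagnosis_text")
        return missing


@dataclass(frozen=True)
class CompleteCaseReport:
    """Accounting of the complete-case screen: every record retained or listed."""

    n_screened: int
    n_included: int
    excluded_ids: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        if self.n_included > self.n_screened:
            raise CohortError("n_included cannot exceed n_screened")
        if self.n_included + len(self.excluded_ids) != self.n_screened:
            raise CohortError("report does not account for every screened record")


@dataclass(frozen=True)
class TableDialect:
    """Delimiter plus a mapping from canonical field names to file headers."""

    delimiter: str = ","
    columns: Mapping[str, str] = field(default_factory=dict)

    def header_for(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableDialect":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        delimiter = raw.get("delimiter", ",")
        if delimiter == "tab":
            delimiter = "\t"
        columns = raw.get("columns", {}) or {}
        unknown = set(columns) - set(_COLUMNS)
        if unknown:
            raise CohortError(f"dialect maps unknown fields: {sorted(unknown)}")
        return cls(delimiter=delimiter, columns=columns)


def _parse_number(cell: object, field_name: str, patient_id: str, row: int) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortError(
            f"row {row} (patient {patient_id!r}): malformed numeric cell "
            f"{text!r} in column {field_name!r}"
        ) from None


def read_cohort(path: str | Path, dialect: TableDialect | None = None) -> list[PatientRecord]:
    """Read a delimited patient table into validated records.

    Empty cells become missing values. Malformed numeric cells and duplicate
    patient ids raise :class:`CohortError` naming the offending row.
    """
    dialect = dialect or TableDialect()
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = {dialect.header_for("patient_id"), dialect.header_for("age"),
                dialect.header_for("sex")}
    missing_headers = required - set(frame.columns)
    if missing_headers:
        raise CohortError(f"table is missing required columns: {sorted(missing_headers)}")

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for row_index, row in enumerate(frame.to_dict("records"), start=1):
        def cell(canonical: str) -> str:
            return str(row.get(dialect.header_for(canonical), "")).strip()

        patient_id = cell("patient_id")
        if patient_id in seen:
            raise CohortError(f"row {row_index}: duplicate patient_id {patient_id!r}")
        seen.add(patient_id)

        numbers = {
            name: _parse_number(cell(name), name, patient_id, row_index)
            for name in _NUMERIC_FIELDS
        }
        age = numbers.pop("age")
        if age is None:
            raise CohortError(f"row {row_index} (patient {patient_id!r}): age is required")
        meds_cell = cell("n_medications")
        if meds_cell == "":
            n_medications = None
        else:
            try:
                n_medications = int(float(meds_cell))
            except ValueError:
                raise CohortError(
                    f"row {row_index} (patient {patient_id!r}): malformed medication count "
                    f"{meds_cell!r}"
                ) from None
        dialysis = cell("dialysis_flag").lower() in ("1", "true", "yes")
        try:
            record = PatientRecord(
                patient_id=patient_id,
                age=age,
                sex=cell("sex").lower(),
                n_medications=n_medications,
                diagnosis_text=cell("diagnosis_text"),
                medication_text=cell("medication_text"),
                dialysis_flag=dialysis,
                **numbers,
            )
        except CohortError as err:
            raise CohortError(f"row {row_index}: {err}") from None
        records.append(record)
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path,
                 dialect: TableDialect | None = None) -> None:
    """Write records to a delimited table; missing values become empty cells."""
    dialect = dialect or TableDialect()
    rows = []
    for rec in records:
        rows.append({
            dialect.header_for("patient_id"): rec.patient_id,
            dialect.header_for("age"): repr(rec.age),
            dialect.header_for("sex"): rec.sex,
            dialect.header_for("creatinine"): "" if rec.creatinine is None else repr(rec.creatinine),
            dialect.header_for("glucose"): "" if rec.glucose is None else repr(rec.glucose),
            dialect.header_for("triglycerides"): "" if rec.triglycerides is None else repr(rec.triglycerides),
            dialect.header_for("uacr"): "" if rec.uacr is None else repr(rec.uacr),
            dialect.header_for("n_medications"): "" if rec.n_medications is None else str(rec.n_medications),
            dialect.header_for("diagnosis_text"): rec.diagnosis_text,
            dialect.header_for("medication_text"): rec.medication_text,
            dialect.header_for("dialysis_flag"): "true" if rec.dialysis_flag else "false",
        })
    frame = pd.DataFrame(rows, columns=[dialect.header_for(c) for c in _COLUMNS])
    frame.to_csv(path, sep=dialect.delimiter, index=False)


def complete_case_filter(
    records: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], CompleteCaseReport]:
    """Retain records with glucose, triglycerides, creatinine and diagnosis text.

    This is the inclusion triplet for index computation: the two TyG labs,
    creatinine for eGFR estimation, and a non-empty diagnostic text field.
    Filtering is idempotent and never raises; every screened record is
    accounted for in the report.
    """
    retained: list[PatientRecord] = []
    excluded: list[tuple[str, tuple[str, ...]]] = []
    for rec in records:
        missing = rec.missing_fields()
        if missing:
            excluded.append((rec.patient_id, tuple(missing)))
        else:
            retained.append(rec)
    report = CompleteCaseReport(
        n_screened=len(records),
        n_included=len(retained),
        excluded_ids=tuple(excluded),
    )
    return retained, report


def with_fields(record: PatientRecord, **changes) -> PatientRecord:
    """Functional update helper (records are frozen)."""
    return replace(record, **changes)
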