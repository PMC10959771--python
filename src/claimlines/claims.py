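"""Patient-level claims data model and CSV I/O.

The layout mirrors a linked administrative claims extract: a demographics
table, a pharmacy dispensing table and a hospital diagnosis table, joined by
``patient_id``.  Four files make up one claims set::

    demographics.csv  patient_id, sex, birth_date, death_date,
                      last_record_date, trial_flag
    dispensing.csv    patient_id, date, drug, days_supply
    diagnoses.csv     patient_id, date, icd10
    metadata.json     optional; study window and provenance notes

Dates are ISO-8601 at day precision.  A dispensing covers the closed day
interval ``[date, date + days_supply - 1]``.  Reading and writing are exact
inverses on valid bundles.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .codesets import CodeValidationError, normalize_icd10

__all__ = [
    "DispensingEvent",
    "DiagnosisEvent",
    "PatientBundle",
    "ClaimsSchemaError",
    "read_claims",
    "write_claims",
    "read_procedures",
    "write_procedures",
]

DEMOGRAPHICS_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "death_date",
    "last_record_date",
    "trial_flag",
]
DISPENSING_COLUMNS = ["patient_id", "date", "drug", "days_supply"]
DIAGNOSES_COLUMNS = ["patient_id", "date", "icd10"]


class ClaimsSchemaError(ValueError):
    """Schema or invariant violation on load, with offending rows listed."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "claims files failed validation:\n  " + "\n  ".join(self.problems)
        )


@dataclass(frozen=True, order=True)
class DispensingEvent:
    """One pharmacy dispensing: a drug identifier with a supply duration."""

    patient_id: str
    date: dt.date
    drug: str
    days_supply: int = 30

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(
                f"days_supply must be >= 1, got {self.days_supply} "
                f"({self.patient_id} {self.date})"
            )
        if not self.drug:
            raise ValueError(f"empty drug identifier ({self.patient_id} {self.date})")

    @property
    def coverage_end(self) -> dt.date:
        """Last day covered by this dispensing (inclusive)."""
        return self.date + dt.timedelta(days=self.days_supply - 1)


@dataclass(frozen=True, order=True)
class DiagnosisEvent:
    """One coded hospital diagnosis."""

    patient_id: str
    date: dt.date
    icd10: str

    def __post_init__(self) -> None:
        normalize_icd10(self.icd10)  # raises on malformed codes


@dataclass(frozen=True)
class PatientBundle:
    """One patient's demographics plus date-sorted event streams.

    Events are totally ordered by (date, stream, code): on the same day a
    diagnosis sorts before a dispensing, then alphabetically by code — so
    identical inputs always yield identical layouts.
    """

    patient_id: str
    sex: str
    birth_date: dt.date
    death_date: dt.date | None
    last_record_date: dt.date
    trial_flag: bool = False
    dispensings: tuple[DispensingEvent, ...] = field(default=())
    diagnoses: tuple[DiagnosisEvent, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        object.__setattr__(
            self,
            "dispensings",
            tuple(sorted(self.dispensings, key=lambda e: (e.date, e.drug, e.days_supply))),
        )
        object.__setattr__(
            self,
            "diagnoses",
            tuple(sorted(self.diagnoses, key=lambda e: (e.date, e.icd10))),
        )

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when the bundle is valid)."""
        problems = []
        bound = self.last_record_date
        if self.death_date is not None:
            bound = min(bound, self.death_date)
        for ev in (*self.dispensings, *self.diagnoses):
            if ev.patient_id != self.patient_id:
                problems.append(
                    f"{self.patient_id}: event with foreign patient_id {ev.patient_id}"
                )
            if ev.date > bound:
                problems.append(
                    f"{self.patient_id}: event on {ev.date} after "
                    f"death/last record {bound}"
                )
        return problems

    def with_events(
        self,
        dispensings: Iterable[DispensingEvent] = (),
        diagnoses: Iterable[DiagnosisEvent] = (),
    ) -> "PatientBundle":
        return replace(
            self,
            dispensings=tuple(self.dispensings) + tuple(dispensings),
            diagnoses=tuple(self.diagnoses) + tuple(diagnoses),
        )


def _parse_date(value, col: str, row: int, problems: list[str]) -> dt.date | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError:
        problems.append(f"{col} row {row}: unparseable date {value!r}")
        return None


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> list[str]:
    missing = [c for c in required if c not in df.columns]
    return [f"{name}: missing required column {c!r}" for c in missing]


def read_claims(directory: str | Path, validate: bool = True) -> list[PatientBundle]:
    """Load a claims CSV set into one :class:`PatientBundle` per patient.

    Parameters
    ----------
    directory
        Folder containing ``demographics.csv`` (required) and optionally
        ``dispensing.csv`` / ``diagnoses.csv``; absent event files yield
        empty streams.
    validate
        When true (default), schema problems and bundle-invariant violations
        raise :class:`ClaimsSchemaError` listing every offending row.
    """
    directory = Path(directory)
    demo_path = directory / "demographics.csv"
    if not demo_path.exists():
        raise FileNotFoundError(f"missing demographics.csv in {directory}")
    problems: list[str] = []

    demo = pd.read_csv(demo_path, dtype=str, keep_default_na=False)
    problems += _check_columns(demo, DEMOGRAPHICS_COLUMNS, "demographics.csv")

    disp_path = directory / "dispensing.csv"
    if disp_path.exists():
        disp = pd.read_csv(disp_path, dtype=str, keep_default_na=False)
        problems += _check_columns(disp, DISPENSING_COLUMNS, "dispensing.csv")
    else:
        disp = pd.DataFrame(columns=DISPENSING_COLUMNS)

    diag_path = directory / "diagnoses.csv"
    if diag_path.exists():
        diag = pd.read_csv(diag_path, dtype=str, keep_default_na=False)
        problems += _check_columns(diag, DIAGNOSES_COLUMNS, "diagnoses.csv")
    else:
        diag = pd.DataFrame(columns=DIAGNOSES_COLUMNS)

    if problems:
        raise ClaimsSchemaError(problems)

    dispensings: dict[str, list[DispensingEvent]] = {}
    for i, row in enumerate(disp.itertuples(index=False), start=2):
        date = _parse_date(row.date, "dispensing.csv", i, problems)
        if date is None:
            continue
        try:
            supply = int(row.days_supply)
            ev = DispensingEvent(row.patient_id, date, row.drug, supply)
        except (ValueError, TypeError) as exc:
            problems.append(f"dispensing.csv row {i}: {exc}")
            continue
        dispensings.setdefault(row.patient_id, []).append(ev)

    diagnoses: dict[str, list[DiagnosisEvent]] = {}
    for i, row in enumerate(diag.itertuples(index=False), start=2):
        date = _parse_date(row.date, "diagnoses.csv", i, problems)
        if date is None:
            continue
        try:
            ev = DiagnosisEvent(row.patient_id, date, row.icd10)
        except CodeValidationError as exc:
            problems.append(f"diagnoses.csv row {i}: {exc}")
            continue
        diagnoses.setdefault(row.patient_id, []).append(ev)

    bundles: list[PatientBundle] = []
    for i, row in enumerate(demo.itertuples(index=False), start=2):
        birth = _parse_date(row.birth_date, "demographics.csv", i, problems)
        last = _parse_date(row.last_record_date, "demographics.csv", i, problems)
        death = _parse_date(row.death_date, "demographics.csv", i, problems)
        if birth is None or last is None:
            problems.append(f"demographics.csv row {i}: missing birth/last record date")
            continue
        try:
            bundle = PatientBundle(
                patient_id=row.patient_id,
                sex=row.sex,
                birth_date=birth,
                death_date=death,
                last_record_date=last,
                trial_flag=str(row.trial_flag).strip().lower() in ("1", "true", "t"),
                dispensings=tuple(dispensings.pop(row.patient_id, ())),
                diagnoses=tuple(diagnoses.pop(row.patient_id, ())),
            )
        except ValueError as exc:
            problems.append(f"demographics.csv row {i}: {exc}")
            continue
        bundles.append(bundle)

    for pid in sorted(set(dispensings) | set(diagnoses)):
        problems.append(f"events for patient {pid!r} with no demographics row")
    if validate:
        for bundle in bundles:
            problems.extend(bundle.validate())
    if problems and validate:
        raise ClaimsSchemaError(problems)
    return bundles


def write_claims(
    bundles: Iterable[PatientBundle],
    directory: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write bundles as the four-file CSV set; inverse of :func:`read_claims`.

    Empty collections still produce valid header-only files.  Returns the
    written paths keyed by table name.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundles = sorted(bundles, key=lambda b: b.patient_id)

    demo_rows, disp_rows, diag_rows = [], [], []
    for b in bundles:
        demo_rows.append(
            {
                "patient_id": b.patient_id,
                "sex": b.sex,
                "birth_date": b.birth_date.isoformat(),
                "death_date": b.death_date.isoformat() if b.death_date else "",
                "last_record_date": b.last_record_date.isoformat(),
                "trial_flag": str(b.trial_flag).lower(),
            }
        )
        for ev in b.dispensings:
            disp_rows.append(
                {
                    "patient_id": ev.patient_id,
                    "date": ev.date.isoformat(),
                    "drug": ev.drug,
                    "days_supply": ev.days_supply,
                }
            )
        for ev in b.diagnoses:
            diag_rows.append(
                {
                    "patient_id": ev.patient_id,
                    "date": ev.date.isoformat(),
                    "icd10": ev.icd10,
                }
            )

    paths = {}
    for name, rows, cols in (
        ("demographics", demo_rows, DEMOGRAPHICS_COLUMNS),
        ("dispensing", disp_rows, DISPENSING_COLUMNS),
        ("diagnoses", diag_rows, DIAGNOSES_COLUMNS),
    ):
        path = directory / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    if metadata is not None:
        meta_path = directory / "metadata.json"
        meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
        paths["metadata"] = meta_path
    return paths


PROCEDURES_COLUMNS = ["patient_id", "date", "kind"]


def read_procedures(directory: str | Path) -> dict[str, list[tuple[dt.date, str]]]:
    """Load the optional ``procedures.csv`` (radiotherapy/surgery markers).

    An absent file yields an empty mapping — procedure-based history flags
    then default to false.
    """
    path = Path(directory) / "procedures.csv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    problems = _check_columns(df, PROCEDURES_COLUMNS, "procedures.csv")
    if problems:
        raise ClaimsSchemaError(problems)
    out: dict[str, list[tuple[dt.date, str]]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(row.date, "procedures.csv", i, problems)
        if date is None:
            raise ClaimsSchemaError(problems)
        out.setdefault(row.patient_id, []).append((date, row.kind))
    return out


def write_procedures(
    procedures: dict[str, Iterable[tuple[dt.date, str]]], directory: str | Path
) -> Path:
    """Write the optional procedures table; inverse of :func:`read_procedures`."""
    path = Path(directory) / "procedures.csv"
    rows = [
        {"patient_id": pid, "date": date.isoformat(), "kind": kind}
        for pid in sorted(procedures)
        for date, kind in sorted(procedures[pid])
    ]
    pd.DataFrame(rows, columns=PROCEDURES_COLUMNS).to_csv(path, index=False)
    return path
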