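"""Readers and writers for the delimited event-table interchange format.

Four UTF-8, comma-delimited files with mandatory headers make up one
claims extract:

* ``events.csv``      patient_id,date,kind,system,code,setting,provider,confirmed
* ``stays.csv``       patient_id,admission,discharge,mode
* ``patients.csv``    patient_id,birth_year,gender,municipality
* ``enrollment.csv``  patient_id,start,end

Writing is deterministic (fixed column order, rows sorted by patient,
date, kind) and byte-stable, so identical inputs produce identical
files; reading flags -- but keeps -- events dated outside every
enrollment interval, and collects malformed rows with their line
numbers instead of dropping them silently.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

from .codes import CodeSystem
from .model import (
    ClaimEvent,
    EventKind,
    Gender,
    HospitalStay,
    PatientRecord,
    Provider,
    Region,
    Setting,
    StayMode,
)

__all__ = [
    "ClaimsSchemaError",
    "ClaimsRowErrors",
    "RowError",
    "read_claims",
    "write_claims",
    "EVENT_COLUMNS",
    "STAY_COLUMNS",
    "PATIENT_COLUMNS",
    "ENROLLMENT_COLUMNS",
]

EVENT_COLUMNS = ["patient_id", "date", "kind", "system", "code", "setting", "provider", "confirmed"]
STAY_COLUMNS = ["patient_id", "admission", "discharge", "mode"]
PATIENT_COLUMNS = ["patient_id", "birth_year", "gender", "municipality"]
ENROLLMENT_COLUMNS = ["patient_id", "start", "end"]


class ClaimsSchemaError(ValueError):
    """A mandatory column is missing from an input file."""


@dataclass(frozen=True)
class RowError:
    file: str
    line: int
    message: str

    def __str__(self) -> str:
        return f"{self.file}:{self.line}: {self.message}"


class ClaimsRowErrors(ValueError):
    """One or more rows could not be parsed."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        super().__init__(
            "; ".join(str(e) for e in errors[:5])
            + (f" (+{len(errors) - 5} more)" if len(errors) > 5 else "")
        )


def _check_header(reader: csv.DictReader, required: list[str], name: str) -> None:
    have = set(reader.fieldnames or [])
    missing = [c for c in required if c not in have]
    if missing:
        raise ClaimsSchemaError(f"{name}: missing mandatory column(s) {missing}")


def _date(s: str) -> dt.date:
    return dt.date.fromisoformat(s.strip())


def read_claims(
    directory: str | Path, strict: bool = True
) -> list[PatientRecord] | tuple[list[PatientRecord], list[RowError]]:
    """Load a claims extract from *directory* into patient records.

    Every parseable input row lands in exactly one record; events are
    sorted and flagged against enrollment.  With ``strict`` (default),
    malformed rows raise :class:`ClaimsRowErrors` carrying file and line
    numbers; with ``strict=False`` the errors are returned alongside the
    records instead.
    """
    directory = Path(directory)
    errors: list[RowError] = []
    records: dict[str, PatientRecord] = {}

    def rec(pid: str) -> PatientRecord:
        if pid not in records:
            records[pid] = PatientRecord(patient_id=pid)
        return records[pid]

    # patients.csv -------------------------------------------------------
    with open(directory / "patients.csv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, PATIENT_COLUMNS, "patients.csv")
        for i, row in enumerate(reader, start=2):
            try:
                r = rec(row["patient_id"])
                by = row["birth_year"].strip()
                r.birth_year = int(by) if by else None
                r.gender = Gender(row["gender"])
                r.municipality = Region(row["municipality"])
            except (ValueError, KeyError) as exc:
                errors.append(RowError("patients.csv", i, str(exc)))

    # enrollment.csv -----------------------------------------------------
    with open(directory / "enrollment.csv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, ENROLLMENT_COLUMNS, "enrollment.csv")
        for i, row in enumerate(reader, start=2):
            try:
                rec(row["patient_id"]).enrollment.append(
                    (_date(row["start"]), _date(row["end"]))
                )
            except ValueError as exc:
                errors.append(RowError("enrollment.csv", i, str(exc)))

    # events.csv ---------------------------------------------------------
    with open(directory / "events.csv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, EVENT_COLUMNS, "events.csv")
        for i, row in enumerate(reader, start=2):
            try:
                system = row["system"].strip()
                code = row["code"].strip()
                rec(row["patient_id"]).events.append(
                    ClaimEvent(
                        patient_id=row["patient_id"],
                        date=_date(row["date"]),
                        kind=EventKind(row["kind"]),
                        system=CodeSystem(system) if system else None,
                        code=code or None,
                        setting=Setting(row["setting"] or "none"),
                        provider=Provider(row["provider"] or "unknown"),
                        confirmed=row["confirmed"].strip() in ("1", "true", "True"),
                    )
                )
            except ValueError as exc:
                errors.append(RowError("events.csv", i, str(exc)))

    # stays.csv ----------------------------------------------------------
    with open(directory / "stays.csv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, STAY_COLUMNS, "stays.csv")
        for i, row in enumerate(reader, start=2):
            try:
                rec(row["patient_id"]).stays.append(
                    HospitalStay(
                        patient_id=row["patient_id"],
                        admission=_date(row["admission"]),
                        discharge=_date(row["discharge"]),
                        mode=StayMode(row["mode"]),
                    )
                )
            except ValueError as exc:
                errors.append(RowError("stays.csv", i, str(exc)))

    out = [records[pid].sort().flag_enrollment() for pid in sorted(records)]
    if errors and strict:
        raise ClaimsRowErrors(errors)
    if strict:
        return out
    return out, errors


def write_claims(records: list[PatientRecord], directory: str | Path) -> list[Path]:
    """Write records as the four-file extract; byte-stable given equal input."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = sorted((r.sort() for r in records), key=lambda r: r.patient_id)
    paths = []

    def _open(name: str):
        p = directory / name
        paths.append(p)
        return open(p, "w", newline="", encoding="utf-8")

    with _open("patients.csv") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PATIENT_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    "" if r.birth_year is None else r.birth_year,
                    r.gender.value,
                    r.municipality.value,
                ]
            )

    with _open("enrollment.csv") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(ENROLLMENT_COLUMNS)
        for r in records:
            for s, e in r.enrollment:
                w.writerow([r.patient_id, s.isoformat(), e.isoformat()])

    with _open("events.csv") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(EVENT_COLUMNS)
        for r in records:
            for ev in r.events:
                w.writerow(
                    [
                        ev.patient_id,
                        ev.date.isoformat(),
                        ev.kind.value,
                        ev.system.value if ev.system else "",
                        ev.code or "",
                        ev.setting.value,
                        ev.provider.value,
                        int(ev.confirmed),
                    ]
                )

    with _open("stays.csv") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(STAY_COLUMNS)
        for r in records:
            for s in r.stays:
                w.writerow([r.patient_id, s.admission.isoformat(), s.discharge.isoformat(), s.mode.value])

    return paths
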