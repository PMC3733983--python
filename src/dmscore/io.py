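"""CSV interchange for cohorts.

Two tables describe a cohort:

``patients.csv``
    patient_id, birth_date, sex, payer

``events.csv``
    one long table with columns patient_id, date, setting, kind, code,
    test_kind, value, units, med_class, history_source — unused columns are
    left empty per row.  This mirrors the shape of a typical flat EHR
    extract and keeps single-file interchange simple.

A third optional table, ``gold.csv`` (patient_id, gold_category, gold_date),
carries physician-adjudicated labels for validation.

Malformed rows are never silently dropped: :func:`read_events` collects them
into a row-level error report (1-based line numbers counted from the header)
and loads everything else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Optional, Sequence, Union

from .model import (
    CareSetting,
    DiagnosisCode,
    EhrEvent,
    EventKind,
    GoldLabel,
    HistoryEntry,
    HistorySource,
    LabKind,
    LabResult,
    MedClass,
    MedicationOrder,
    Patient,
    PatientTimeline,
    Payer,
    Sex,
    assemble_timelines,
)

EVENT_COLUMNS = [
    "patient_id",
    "date",
    "setting",
    "kind",
    "code",
    "test_kind",
    "value",
    "units",
    "med_class",
    "history_source",
]

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "payer"]

GOLD_COLUMNS = ["patient_id", "gold_category", "gold_date"]


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based, header = line 1
    message: str


@dataclass
class ReadReport:
    """Result of reading an events file: timelines plus any rejected rows."""

    timelines: list[PatientTimeline]
    errors: list[RowError] = field(default_factory=list)

    @property
    def n_loaded(self) -> int:
        return sum(len(t.events) for t in self.timelines)


def _parse_date(text: str) -> Date:
    return Date.fromisoformat(text.strip())


def _require_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_event_row(row: dict[str, str]) -> EhrEvent:
    pid = row["patient_id"].strip()
    if not pid:
        raise ValueError("empty patient_id")
    date = _parse_date(row["date"])
    try:
        setting = CareSetting(row["setting"].strip())
    except ValueError:
        raise ValueError(f"unknown setting {row['setting']!r}")
    try:
        kind = EventKind(row["kind"].strip())
    except ValueError:
        raise ValueError(f"unknown kind {row['kind']!r}")

    if kind is EventKind.ENCOUNTER_DX:
        payload = DiagnosisCode(code=row["code"].strip())
    elif kind is EventKind.LAB:
        try:
            test_kind = LabKind(row["test_kind"].strip())
        except ValueError:
            raise ValueError(f"unknown test_kind {row['test_kind']!r}")
        payload = LabResult(
            test_kind=test_kind,
            value=float(row["value"]),
            units=row["units"].strip(),
        )
    elif kind is EventKind.MEDICATION:
        try:
            med_class = MedClass(row["med_class"].strip())
        except ValueError:
            raise ValueError(f"unknown med_class {row['med_class']!r}")
        payload = MedicationOrder(med_class=med_class)
    else:  # history
        try:
            source = HistorySource(row["history_source"].strip())
        except ValueError:
            raise ValueError(f"unknown history_source {row['history_source']!r}")
        payload = HistoryEntry(source=source, code=row["code"].strip())

    return EhrEvent(patient_id=pid, date=date, setting=setting, kind=kind, payload=payload)


def read_events(
    events_path: Union[str, Path],
    patients_path: Optional[Union[str, Path]] = None,
) -> ReadReport:
    """Read an events CSV (and optionally a patients CSV) into timelines.

    Patients absent from ``patients_path`` (or when no patients file is
    given) are synthesised with a placeholder birth date, since demographics
    never affect scoring.  Rows that fail to parse are reported with their
    line number; the rest of the file still loads.
    """
    events_path = Path(events_path)
    patients: dict[str, Patient] = {}
    if patients_path is not None:
        for p in read_patients(patients_path):
            if p.patient_id in patients:
                raise ValueError(f"duplicate patient_id {p.patient_id!r}")
            patients[p.patient_id] = p

    events: list[EhrEvent] = []
    errors: list[RowError] = []
    with open(events_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{events_path}: empty file, no header")
        _require_columns(reader.fieldnames, EVENT_COLUMNS, events_path)
        for lineno, row in enumerate(reader, start=2):
            try:
                events.append(_parse_event_row(row))
            except (ValueError, TypeError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))

    for ev in events:
        if ev.patient_id not in patients:
            patients[ev.patient_id] = Patient(
                patient_id=ev.patient_id, birth_date=Date(1900, 1, 1)
            )
    timelines = assemble_timelines(patients.values(), events)
    return ReadReport(timelines=timelines, errors=errors)


def write_events(cohort: Sequence[PatientTimeline], path: Union[str, Path]) -> None:
    """Write all events of a cohort to one long CSV (round-trips with
    :func:`read_events`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
        writer.writeheader()
        for tl in cohort:
            for ev in tl.events:
                row = {c: "" for c in EVENT_COLUMNS}
                row["patient_id"] = ev.patient_id
                row["date"] = ev.date.isoformat()
                row["setting"] = ev.setting.value
                row["kind"] = ev.kind.value
                p = ev.payload
                if ev.kind is EventKind.ENCOUNTER_DX:
                    row["code"] = p.code
                elif ev.kind is EventKind.LAB:
                    row["test_kind"] = p.test_kind.value
                    row["value"] = repr(p.value)
                    row["units"] = p.units
                elif ev.kind is EventKind.MEDICATION:
                    row["med_class"] = p.med_class.value
                else:
                    row["history_source"] = p.source.value
                    row["code"] = p.code
                writer.writerow(row)


def read_patients(path: Union[str, Path]) -> list[Patient]:
    out: list[Patient] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _require_columns(reader.fieldnames, ["patient_id", "birth_date"], path)
        for row in reader:
            sex = Sex(row["sex"].strip()) if row.get("sex", "").strip() else Sex.OTHER
            payer_txt = row.get("payer", "").strip()
            payer = Payer(payer_txt) if payer_txt else None
            out.append(
                Patient(
                    patient_id=row["patient_id"].strip(),
                    birth_date=_parse_date(row["birth_date"]),
                    sex=sex,
                    payer=payer,
                )
            )
    return out


def write_patients(cohort: Sequence[PatientTimeline], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PATIENT_COLUMNS)
        writer.writeheader()
        for tl in cohort:
            p = tl.patient
            writer.writerow(
                {
                    "patient_id": p.patient_id,
                    "birth_date": p.birth_date.isoformat(),
                    "sex": p.sex.value,
                    "payer": p.payer.value if p.payer else "",
                }
            )


def read_gold(path: Union[str, Path]) -> list[GoldLabel]:
    out: list[GoldLabel] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _require_columns(reader.fieldnames, GOLD_COLUMNS, path)
        for row in reader:
            date_txt = row["gold_date"].strip()
            out.append(
                GoldLabel(
                    patient_id=row["patient_id"].strip(),
                    category=row["gold_category"].strip(),
                    date=_parse_date(date_txt) if date_txt else None,
                )
            )
    return out


def write_gold(labels: Sequence[GoldLabel], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=GOLD_COLUMNS)
        writer.writeheader()
        for g in labels:
            writer.writerow(
                {
                    "patient_id": g.patient_id,
                    "gold_category": g.category,
                    "gold_date": g.date.isoformat() if g.date else "",
                }
            )
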