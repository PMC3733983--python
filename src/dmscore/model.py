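"""Domain types for patients and dated EHR events.

The unit of analysis is a :class:`PatientTimeline`: a patient plus a
date-sorted stream of typed clinical facts (encounter diagnosis codes,
laboratory results, medication orders, and problem-list / past-medical-history
entries), each tagged with the care setting in which it was recorded.
Dates are calendar dates; intra-day ordering is never semantically
significant, and all downstream logic is defined so that permuting
same-date events cannot change any result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date as Date
from enum import Enum
from typing import Iterable, Optional, Union

__all__ = [
    "CareSetting",
    "EventKind",
    "Sex",
    "Payer",
    "HistorySource",
    "LabKind",
    "MedClass",
    "DiagnosisCode",
    "LabResult",
    "MedicationOrder",
    "HistoryEntry",
    "EhrEvent",
    "Patient",
    "PatientTimeline",
    "GoldLabel",
    "is_icd9_code",
]


class CareSetting(str, Enum):
    """Care setting of an event; scoring criteria restrict on this."""

    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    EMERGENCY_URGENT = "emergency_urgent"


class EventKind(str, Enum):
    ENCOUNTER_DX = "encounter_dx"
    LAB = "lab"
    MEDICATION = "medication"
    HISTORY = "history"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    OTHER = "other"


class Payer(str, Enum):
    COMMERCIAL = "commercial"
    MEDICARE = "medicare"
    MEDICAID = "medicaid"
    SELF_PAY = "self_pay"
    CHARITY = "charity"
    OTHER = "other"


class HistorySource(str, Enum):
    PROBLEM_LIST = "problem_list"
    PAST_MEDICAL_HISTORY = "past_medical_history"


class LabKind(str, Enum):
    HBA1C = "hba1c"
    FASTING_GLUCOSE = "fasting_glucose"
    RANDOM_GLUCOSE = "random_glucose"
    OGTT_2H = "ogtt_2h"


#: Canonical units per laboratory test kind.  HbA1c is a percentage of total
#: hemoglobin; plasma glucoses are mg/dL.  No unit conversion is attempted —
#: mismatched units are a hard error, never silently rescaled.
LAB_UNITS = {
    LabKind.HBA1C: "%",
    LabKind.FASTING_GLUCOSE: "mg/dL",
    LabKind.RANDOM_GLUCOSE: "mg/dL",
    LabKind.OGTT_2H: "mg/dL",
}


class MedClass(str, Enum):
    METFORMIN = "metformin"
    OTHER_DIABETES_MEDICATION = "other_diabetes_medication"
    NON_DIABETES_MEDICATION = "non_diabetes_medication"


_ICD9_RE = re.compile(r"^(?:\d{1,3}(?:\.\d{0,2})?|[VE]\d{1,4}(?:\.\d{0,2})?)$")


def is_icd9_code(code: str) -> bool:
    """Lexical check for an ICD-9-CM code: numeric category with optional
    dotted subdivision, or a V/E-prefixed code.  ``"250"``, ``"250.0"`` and
    ``"250.00"`` are valid; ``"2500"`` (no dot) is not a diabetes code."""
    return bool(_ICD9_RE.match(code))


@dataclass(frozen=True)
class DiagnosisCode:
    """An ICD-9-CM encounter diagnosis code, e.g. ``"250.00"``."""

    code: str

    def __post_init__(self) -> None:
        if not self.code or not is_icd9_code(self.code):
            raise ValueError(f"not a valid ICD-9 code: {self.code!r}")


@dataclass(frozen=True)
class LabResult:
    """A laboratory result with its test kind, numeric value and units."""

    test_kind: LabKind
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"lab value must be positive, got {self.value}")


@dataclass(frozen=True)
class MedicationOrder:
    med_class: MedClass


@dataclass(frozen=True)
class HistoryEntry:
    """A diabetes-relevant entry on the problem list or past medical history."""

    source: HistorySource
    code: str

    def __post_init__(self) -> None:
        if not self.code or not is_icd9_code(self.code):
            raise ValueError(f"not a valid ICD-9 code: {self.code!r}")


Payload = Union[DiagnosisCode, LabResult, MedicationOrder, HistoryEntry]

_KIND_PAYLOAD = {
    EventKind.ENCOUNTER_DX: DiagnosisCode,
    EventKind.LAB: LabResult,
    EventKind.MEDICATION: MedicationOrder,
    EventKind.HISTORY: HistoryEntry,
}


@dataclass(frozen=True)
class EhrEvent:
    """One dated, setting-tagged clinical fact for one patient."""

    patient_id: str
    date: Date
    setting: CareSetting
    kind: EventKind
    payload: Payload

    def __post_init__(self) -> None:
        expected = _KIND_PAYLOAD[self.kind]
        if not isinstance(self.payload, expected):
            raise TypeError(
                f"event kind {self.kind.value} requires payload "
                f"{expected.__name__}, got {type(self.payload).__name__}"
            )


@dataclass(frozen=True)
class Patient:
    """Demographics are carried for cohort summaries and the age restriction
    used in chart-review sampling; they never enter scoring."""

    patient_id: str
    birth_date: Date
    sex: Sex = Sex.OTHER
    payer: Optional[Payer] = None


@dataclass
class PatientTimeline:
    """A patient and their events, sorted ascending by date (stable)."""

    patient: Patient
    events: list[EhrEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.patient_id != self.patient.patient_id:
                raise ValueError(
                    f"event patient_id {ev.patient_id!r} does not match "
                    f"timeline patient {self.patient.patient_id!r}"
                )
        self.events = sorted(self.events, key=lambda e: e.date)

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id

    def add(self, event: EhrEvent) -> None:
        if event.patient_id != self.patient.patient_id:
            raise ValueError("event belongs to a different patient")
        self.events.append(event)
        self.events.sort(key=lambda e: e.date)


@dataclass(frozen=True)
class GoldLabel:
    """Physician-adjudicated status and, for diabetics, diagnosis date."""

    patient_id: str
    category: str  # one of "none", "possible", "diabetes"
    date: Optional[Date] = None

    def __post_init__(self) -> None:
        if self.category not in ("none", "possible", "diabetes"):
            raise ValueError(f"unknown gold category {self.category!r}")
        if self.category != "diabetes" and self.date is not None:
            raise ValueError("gold date only allowed for category 'diabetes'")


def assemble_timelines(
    patients: Iterable[Patient], events: Iterable[EhrEvent]
) -> list[PatientTimeline]:
    """Group events by patient and build sorted timelines.

    Every event must reference a known patient; patients with no events get
    an empty timeline.  Timelines come back in the order patients were given.
    """
    by_id: dict[str, PatientTimeline] = {}
    for p in patients:
        if p.patient_id in by_id:
            raise ValueError(f"duplicate patient_id {p.patient_id!r}")
        by_id[p.patient_id] = PatientTimeline(patient=p, events=[])
    for ev in events:
        if ev.patient_id not in by_id:
            raise ValueError(f"event references unknown patient {ev.patient_id!r}")
        by_id[ev.patient_id].events.append(ev)
    for tl in by_id.values():
        tl.events.sort(key=lambda e: e.date)
    return list(by_id.values())
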