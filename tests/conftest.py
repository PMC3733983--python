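"""Shared fixtures and factories for building small timelines by hand."""

from __future__ import annotations

from datetime import date as Date, timedelta

import numpy as np
import pytest

from dmscore.model import (
    CareSetting,
    DiagnosisCode,
    EhrEvent,
    EventKind,
    HistoryEntry,
    HistorySource,
    LabKind,
    LabResult,
    MedClass,
    MedicationOrder,
    Patient,
    PatientTimeline,
)

OUT = CareSetting.OUTPATIENT
INP = CareSetting.INPATIENT
ED = CareSetting.EMERGENCY_URGENT


def lab(pid, date, kind, value, setting=OUT, units=None):
    if units is None:
        units = "%" if kind is LabKind.HBA1C else "mg/dL"
    return EhrEvent(pid, date, setting, EventKind.LAB, LabResult(kind, value, units))


def encounter(pid, date, code, setting=OUT):
    return EhrEvent(pid, date, setting, EventKind.ENCOUNTER_DX, DiagnosisCode(code))


def med(pid, date, med_class, setting=OUT):
    return EhrEvent(pid, date, setting, EventKind.MEDICATION, MedicationOrder(med_class))


def history(pid, date, code="250.00", source=HistorySource.PROBLEM_LIST, setting=OUT):
    return EhrEvent(pid, date, setting, EventKind.HISTORY, HistoryEntry(source, code))


def timeline(events, pid="P1", birth=Date(1955, 6, 1)):
    return PatientTimeline(Patient(pid, birth), list(events))


@pytest.fixture
def pid():
    return "P1"


def random_timeline(rng: np.random.Generator, pid: str = "P1") -> PatientTimeline:
    """A small random timeline mixing all event kinds, settings, and values
    both above and below the lab thresholds, over a short date window."""
    n = int(rng.integers(0, 9))
    base = Date(2009, 1, 1)
    events = []
    for _ in range(n):
        d = base + timedelta(days=int(rng.integers(0, 60)))
        setting = [OUT, INP, ED][int(rng.integers(0, 3))]
        kind = int(rng.integers(0, 4))
        if kind == 0:
            code = str(rng.choice(["250.00", "250.50", "250", "401.9", "486"]))
            events.append(encounter(pid, d, code, setting))
        elif kind == 1:
            lk = [LabKind.HBA1C, LabKind.FASTING_GLUCOSE, LabKind.RANDOM_GLUCOSE, LabKind.OGTT_2H][
                int(rng.integers(0, 4))
            ]
            if lk is LabKind.HBA1C:
                value = float(rng.uniform(5.0, 9.0))
            else:
                value = float(rng.uniform(80, 260))
            events.append(lab(pid, d, lk, value, setting))
        elif kind == 2:
            mc = [MedClass.METFORMIN, MedClass.OTHER_DIABETES_MEDICATION, MedClass.NON_DIABETES_MEDICATION][
                int(rng.integers(0, 3))
            ]
            events.append(med(pid, d, mc, setting))
        else:
            code = str(rng.choice(["250.00", "250", "401.9"]))
            src = [HistorySource.PROBLEM_LIST, HistorySource.PAST_MEDICAL_HISTORY][int(rng.integers(0, 2))]
            events.append(history(pid, d, code, src, setting))
    return timeline(events, pid=pid)
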