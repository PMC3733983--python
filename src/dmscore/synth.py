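"""Seeded synthetic EHR cohort generator with known ground truth.

Each patient is drawn from an *archetype* — a template chart that
deterministically implies a gold diabetes status and, for diabetic
archetypes, a gold diagnosis date defined as the earliest date the
generated evidence satisfies the diagnostic point threshold.  Three
archetypes reproduce documented real-world noise modes that motivated the
model's weight recalibration:

* ``prediabetic_metformin`` / ``pcos_metformin`` — metformin prescribed for
  pre-diabetes or polycystic ovarian syndrome in a patient without diabetes;
* ``stale_problem_list`` — an inaccurate or outdated diabetes entry on the
  problem list / past medical history;
* ``miscoded_single_icd9`` — a single isolated 250.xx encounter code with no
  corroborating evidence.

Lab-value distributions are generator conveniences (diabetic HbA1c lognormal
around 7.5–9 %, non-diabetic 5.0–5.6 %, glucoses analogous), not claims
about any real population; they are exposed as archetype parameters.

Randomness: one global integer seed; each patient consumes an independent
substream keyed by (seed, patient index), so cohorts are reproducible and
stable in their prefix when ``n_patients`` grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Optional, Sequence

import numpy as np

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
    Sex,
)
from .scoring import PatientScore

__all__ = [
    "ARCHETYPES",
    "CohortSpec",
    "generate",
    "stratified_sample",
    "age_restrict",
]

ARCHETYPES = (
    "true_diabetic_labs",
    "true_diabetic_meds",
    "true_diabetic_codes",
    "prediabetic_metformin",
    "pcos_metformin",
    "stale_problem_list",
    "miscoded_single_icd9",
    "healthy",
    "healthy_elderly",
)

#: ICD-9 codes used as non-diabetes filler encounters.
_DISTRACTOR_CODES = ("401.9", "486", "724.2", "530.81", "272.4")

#: Mean encounters per patient, echoing a typical ambulatory utilisation
#: level (~6.6 encounters over the study window).
MEAN_ENCOUNTERS = 6.6


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``mix`` maps archetype name to proportion (must sum to 1).
    ``stratification`` optionally notes the chart-review sampling design this
    cohort is destined for ("derivation_50_25_25", "validation_50_10_40");
    it is metadata only — apply :func:`stratified_sample` to realise it.
    """

    n_patients: int
    mix: dict[str, float]
    start: Date = Date(2009, 1, 1)
    end: Date = Date(2011, 4, 30)
    seed: int = 0
    stratification: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        unknown = set(self.mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if self.stratification not in (None, "none", "derivation_50_25_25", "validation_50_10_40"):
            raise ValueError(f"unknown stratification {self.stratification!r}")


def _distinct_dates(rng: np.random.Generator, start: Date, end: Date, k: int) -> list[Date]:
    """k distinct calendar dates in [start, end], sorted ascending."""
    span = (end - start).days + 1
    k = min(k, span)
    offsets = rng.choice(span, size=k, replace=False)
    return sorted(start + timedelta(days=int(o)) for o in offsets)


def _lab(pid: str, date: Date, setting: CareSetting, kind: LabKind, value: float) -> EhrEvent:
    units = "%" if kind is LabKind.HBA1C else "mg/dL"
    return EhrEvent(
        patient_id=pid,
        date=date,
        setting=setting,
        kind=EventKind.LAB,
        payload=LabResult(test_kind=kind, value=round(float(value), 1), units=units),
    )


def _encounter(pid: str, date: Date, setting: CareSetting, code: str) -> EhrEvent:
    return EhrEvent(
        patient_id=pid,
        date=date,
        setting=setting,
        kind=EventKind.ENCOUNTER_DX,
        payload=DiagnosisCode(code=code),
    )


def _normal_a1c(rng: np.random.Generator) -> float:
    return float(rng.uniform(5.0, 5.6))


def _normal_fasting(rng: np.random.Generator) -> float:
    return float(rng.uniform(78, 99))


def _diabetic_fasting(rng: np.random.Generator) -> float:
    # lognormal, floor at the 126 mg/dL diagnostic cut-off
    return max(126.0, float(rng.lognormal(mean=np.log(155), sigma=0.15)))


def _diabetic_a1c(rng: np.random.Generator) -> float:
    return max(6.5, float(rng.lognormal(mean=np.log(8.1), sigma=0.10)))


def _filler_events(
    rng: np.random.Generator, pid: str, dates: Sequence[Date]
) -> list[EhrEvent]:
    """Non-diabetes encounters and normal labs that never score points."""
    events = []
    for d in dates:
        code = str(rng.choice(_DISTRACTOR_CODES))
        setting = CareSetting.OUTPATIENT if rng.random() < 0.85 else CareSetting.EMERGENCY_URGENT
        events.append(_encounter(pid, d, setting, code))
        if rng.random() < 0.4:
            events.append(
                _lab(pid, d, CareSetting.OUTPATIENT, LabKind.FASTING_GLUCOSE, _normal_fasting(rng))
            )
    return events


def _birth_date(rng: np.random.Generator, start: Date, age_lo: float, age_hi: float) -> Date:
    age_days = rng.uniform(age_lo * 365.25, age_hi * 365.25)
    return start - timedelta(days=int(age_days))


def _make_patient(
    rng: np.random.Generator,
    pid: str,
    archetype: str,
    start: Date,
    end: Date,
) -> tuple[PatientTimeline, GoldLabel]:
    sex = Sex.FEMALE if archetype == "pcos_metformin" else (
        Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
    )
    if archetype == "healthy_elderly":
        birth = _birth_date(rng, start, 55, 90)
    elif archetype == "pcos_metformin":
        birth = _birth_date(rng, start, 18, 45)
    else:
        birth = _birth_date(rng, start, 25, 85)
    patient = Patient(patient_id=pid, birth_date=birth, sex=sex)

    n_filler = int(rng.poisson(MEAN_ENCOUNTERS))
    events: list[EhrEvent] = []
    gold_category = "none"
    gold_date: Optional[Date] = None

    if archetype == "true_diabetic_labs":
        # diagnosis by repeated outpatient glucose: the second qualifying
        # lab crosses the 1-point threshold and defines the gold date
        k = 2 + int(rng.poisson(1.0))
        lab_dates = _distinct_dates(rng, start, end, k)
        for d in lab_dates:
            if rng.random() < 0.7:
                events.append(
                    _lab(pid, d, CareSetting.OUTPATIENT, LabKind.FASTING_GLUCOSE, _diabetic_fasting(rng))
                )
            else:
                events.append(
                    _lab(
                        pid, d, CareSetting.OUTPATIENT, LabKind.RANDOM_GLUCOSE,
                        max(200.0, float(rng.lognormal(np.log(240), 0.15))),
                    )
                )
        gold_category, gold_date = "diabetes", lab_dates[1]
        # confirmatory HbA1c strictly after the crossing date never moves it
        if rng.random() < 0.5 and gold_date < end:
            later = _distinct_dates(rng, gold_date + timedelta(days=1), end, 1)
            if later:
                events.append(_lab(pid, later[0], CareSetting.OUTPATIENT, LabKind.HBA1C, _diabetic_a1c(rng)))
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype == "true_diabetic_meds":
        # a non-metformin diabetes drug order alone carries the full point
        med_date = _distinct_dates(rng, start, end, 1)[0]
        events.append(
            EhrEvent(
                patient_id=pid, date=med_date, setting=CareSetting.OUTPATIENT,
                kind=EventKind.MEDICATION,
                payload=MedicationOrder(med_class=MedClass.OTHER_DIABETES_MEDICATION),
            )
        )
        gold_category, gold_date = "diabetes", med_date
        # follow-up 250.xx coding strictly after diagnosis
        if med_date < end:
            n_later = int(rng.poisson(1.0))
            for d in _distinct_dates(rng, med_date + timedelta(days=1), end, n_later):
                events.append(_encounter(pid, d, CareSetting.OUTPATIENT, "250.00"))
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype == "true_diabetic_codes":
        k = 2 + int(rng.poisson(1.0))
        code_dates = _distinct_dates(rng, start, end, k)
        for d in code_dates:
            code = str(rng.choice(["250.00", "250.02", "250.60", "250"]))
            setting = CareSetting.OUTPATIENT if rng.random() < 0.8 else CareSetting.INPATIENT
            events.append(_encounter(pid, d, setting, code))
        gold_category, gold_date = "diabetes", code_dates[1]
        # problem-list entry appears only after the coded diagnosis
        if rng.random() < 0.5 and gold_date < end:
            later = _distinct_dates(rng, gold_date + timedelta(days=1), end, 1)
            if later:
                events.append(
                    EhrEvent(
                        patient_id=pid, date=later[0], setting=CareSetting.OUTPATIENT,
                        kind=EventKind.HISTORY,
                        payload=HistoryEntry(source=HistorySource.PROBLEM_LIST, code="250.00"),
                    )
                )
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype in ("prediabetic_metformin", "pcos_metformin"):
        # metformin without diabetes: orders plus sub-threshold glycemia
        for d in _distinct_dates(rng, start, end, 1 + int(rng.poisson(1.0))):
            events.append(
                EhrEvent(
                    patient_id=pid, date=d, setting=CareSetting.OUTPATIENT,
                    kind=EventKind.MEDICATION,
                    payload=MedicationOrder(med_class=MedClass.METFORMIN),
                )
            )
        for d in _distinct_dates(rng, start, end, 1 + int(rng.poisson(0.5))):
            if archetype == "prediabetic_metformin":
                events.append(_lab(pid, d, CareSetting.OUTPATIENT, LabKind.HBA1C, float(rng.uniform(5.7, 6.4))))
            else:
                events.append(_lab(pid, d, CareSetting.OUTPATIENT, LabKind.HBA1C, _normal_a1c(rng)))
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype == "stale_problem_list":
        d = _distinct_dates(rng, start, end, 1)[0]
        events.append(
            EhrEvent(
                patient_id=pid, date=d, setting=CareSetting.OUTPATIENT,
                kind=EventKind.HISTORY,
                payload=HistoryEntry(
                    source=HistorySource.PAST_MEDICAL_HISTORY
                    if rng.random() < 0.5
                    else HistorySource.PROBLEM_LIST,
                    code="250.00",
                ),
            )
        )
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype == "miscoded_single_icd9":
        d = _distinct_dates(rng, start, end, 1)[0]
        events.append(_encounter(pid, d, CareSetting.OUTPATIENT, "250.00"))
        filler = _distinct_dates(rng, start, end, n_filler)
        events += _filler_events(rng, pid, filler)

    elif archetype in ("healthy", "healthy_elderly"):
        filler = _distinct_dates(rng, start, end, max(1, n_filler))
        events += _filler_events(rng, pid, filler)
        if rng.random() < 0.5:
            d = _distinct_dates(rng, start, end, 1)[0]
            events.append(_lab(pid, d, CareSetting.OUTPATIENT, LabKind.HBA1C, _normal_a1c(rng)))

    else:  # pragma: no cover
        raise ValueError(f"unknown archetype {archetype!r}")

    timeline = PatientTimeline(patient=patient, events=events)
    gold = GoldLabel(patient_id=pid, category=gold_category, date=gold_date)
    return timeline, gold


def generate(spec: CohortSpec) -> tuple[list[PatientTimeline], list[GoldLabel]]:
    """Generate a cohort and its gold labels; fully reproducible from the
    spec's seed."""
    names = sorted(spec.mix)
    probs = np.array([spec.mix[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    assign_rng = np.random.default_rng([spec.seed, 0xA55])
    assignments = assign_rng.choice(len(names), size=spec.n_patients, p=probs)

    cohort: list[PatientTimeline] = []
    labels: list[GoldLabel] = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:05d}"
        rng = np.random.default_rng([spec.seed, i + 1])
        tl, gold = _make_patient(rng, pid, names[assignments[i]], spec.start, spec.end)
        cohort.append(tl)
        labels.append(gold)
    return cohort, labels


def stratified_sample(
    cohort: Sequence[PatientTimeline],
    scores: Sequence[PatientScore],
    fractions: dict[str, float],
    n: int,
    seed: int = 0,
) -> list[PatientTimeline]:
    """Sample up to ``n`` patients stratified by model category.

    ``fractions`` maps category ("none" / "possible" / "diabetes") to its
    share of the sample and must sum to 1.  Sampling is without replacement
    within each stratum; a stratum smaller than its quota contributes all
    its members with a warning (the sample is then smaller than ``n``).
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("stratum fractions must sum to 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    by_id = {t.patient_id: t for t in cohort}
    strata: dict[str, list[str]] = {c: [] for c in fractions}
    for s in scores:
        if s.category in strata:
            strata[s.category].append(s.patient_id)

    rng = np.random.default_rng([seed, 0x5A5])
    out: list[PatientTimeline] = []
    for cat in sorted(fractions):
        quota = round(n * fractions[cat])
        members = strata[cat]
        if len(members) < quota:
            warnings.warn(
                f"stratum {cat!r} has only {len(members)} patients for a "
                f"quota of {quota}; taking all of them",
                stacklevel=2,
            )
            chosen = list(members)
        else:
            chosen = [members[i] for i in rng.choice(len(members), size=quota, replace=False)]
        out.extend(by_id[pid] for pid in chosen)
    return out


def age_restrict(
    cohort: Sequence[PatientTimeline],
    scores: Sequence[PatientScore],
    min_age_years: float = 50,
    restrict_category: str = "none",
) -> list[PatientTimeline]:
    """Drop patients in one model stratum who are younger than a minimum age
    at their first encounter (default: the "none" stratum, 50 years).

    Restricting the negative stratum to older patients enriches it for
    plausible undetected cases, sharpening a chart-review evaluation's power
    to find false negatives.  Other strata pass through untouched.
    """
    cat_by_id = {s.patient_id: s.category for s in scores}
    out = []
    for tl in cohort:
        if cat_by_id.get(tl.patient_id) != restrict_category:
            out.append(tl)
            continue
        if not tl.events:
            continue
        first = tl.events[0].date
        age_years = (first - tl.patient.birth_date).days / 365.25
        if age_years >= min_age_years:
            out.append(tl)
    return out
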