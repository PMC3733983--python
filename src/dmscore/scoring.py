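"""The point-based case-finding scorer.

Each patient's events are walked in calendar order; events that satisfy a
criterion (right evidence, right setting, threshold met) contribute that
criterion's weight, subject to its accrual policy.  The running total
classifies the patient three ways — 0 points is "none", anything strictly
between 0 and the diagnosis threshold is "possible", and reaching the
threshold is "diabetes" — and the diagnosis date is the *earliest* calendar
date on which the accumulated points reach the threshold.

All point arithmetic is exact (:class:`decimal.Decimal`); the threshold
comparison involves no floating-point tolerance.  Because contributions are
deduplicated on (criterion, date) and once-per-patient criteria fire on
their first qualifying *date*, the result is invariant under permutation of
same-date events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from decimal import Decimal
from typing import Iterable, Optional, Sequence

from .config import Accrual, Criterion, WeightConfig, default_config
from .model import (
    EhrEvent,
    EventKind,
    LAB_UNITS,
    LabKind,
    MedClass,
    PatientTimeline,
)

__all__ = [
    "Category",
    "ScoreContribution",
    "PatientScore",
    "UnitError",
    "match_event",
    "classify",
    "score_patient",
    "score_cohort",
    "CohortSummary",
]

CATEGORIES = ("none", "possible", "diabetes")
Category = str


class UnitError(ValueError):
    """Lab units inconsistent with the test kind; no silent conversion."""


def _icd9_matches_prefix(code: str, prefix: str) -> bool:
    """Category-level ICD-9 prefix match: ``250``, ``250.0``, ``250.00`` all
    match prefix ``250``; ``2500`` does not (the category is the part before
    the dot)."""
    category = code.split(".", 1)[0]
    return category == prefix


# Criterion name implied by a lab's test kind.
_LAB_CRITERION = {
    LabKind.HBA1C: "hba1c",
    LabKind.FASTING_GLUCOSE: "fasting_glucose",
    LabKind.RANDOM_GLUCOSE: "random_glucose",
    LabKind.OGTT_2H: "ogtt_2h",
}

_MED_CRITERION = {
    MedClass.METFORMIN: "metformin",
    MedClass.OTHER_DIABETES_MEDICATION: "diabetes_medication",
}


def match_event(
    event: EhrEvent, config: WeightConfig
) -> Optional[tuple[Criterion, Decimal]]:
    """Return the (criterion, points) an event satisfies, or ``None``.

    Raises :class:`UnitError` if a lab's units disagree with the canonical
    units for its test kind.
    """
    if event.kind is EventKind.ENCOUNTER_DX:
        name = "icd9_encounter"
    elif event.kind is EventKind.LAB:
        name = _LAB_CRITERION[event.payload.test_kind]
    elif event.kind is EventKind.MEDICATION:
        name = _MED_CRITERION.get(event.payload.med_class)
        if name is None:  # non-diabetes medication
            return None
    else:  # history
        name = "history_dx"

    try:
        crit = config.criterion(name)
    except KeyError:
        return None

    if event.setting not in crit.allowed_settings:
        return None

    if event.kind is EventKind.LAB:
        expected_units = LAB_UNITS[event.payload.test_kind]
        if event.payload.units != expected_units:
            raise UnitError(
                f"lab {event.payload.test_kind.value} reported in "
                f"{event.payload.units!r}, expected {expected_units!r}"
            )
        assert crit.threshold is not None
        if Decimal(str(event.payload.value)) < crit.threshold:
            return None
    elif event.kind is EventKind.ENCOUNTER_DX:
        if crit.code_prefix and not _icd9_matches_prefix(
            event.payload.code, crit.code_prefix
        ):
            return None
    elif event.kind is EventKind.HISTORY:
        if crit.code_prefix and not _icd9_matches_prefix(
            event.payload.code, crit.code_prefix
        ):
            return None

    return crit, crit.weight


def classify(total: Decimal, config: Optional[WeightConfig] = None) -> Category:
    """Three-way classification of a cumulative point total."""
    if config is None:
        config = default_config()
    total = Decimal(str(total)) if not isinstance(total, Decimal) else total
    if total < 0:
        raise ValueError(f"point total must be non-negative, got {total}")
    if total == 0:
        return "none"
    if total < config.diabetes_threshold:
        return "possible"
    return "diabetes"


@dataclass(frozen=True)
class ScoreContribution:
    date: Date
    criterion: str
    points: Decimal
    source_event: EhrEvent


@dataclass
class PatientScore:
    patient_id: str
    contributions: list[ScoreContribution]
    total: Decimal
    category: Category
    diagnosis_date: Optional[Date]


def score_patient(
    timeline: PatientTimeline, config: Optional[WeightConfig] = None
) -> PatientScore:
    """Score one patient: accrue points chronologically, classify, and find
    the earliest date the running total reaches the diagnosis threshold.

    Accrual policy: ``per_distinct_date`` criteria contribute at most once
    per (criterion, date); ``once_per_patient`` criteria contribute only on
    their first qualifying date.
    """
    if config is None:
        config = default_config()

    seen_dates: set[tuple[str, Date]] = set()
    fired_once: set[str] = set()
    contributions: list[ScoreContribution] = []

    for event in sorted(timeline.events, key=lambda e: e.date):
        try:
            match = match_event(event, config)
        except UnitError as exc:
            raise UnitError(
                f"patient {timeline.patient_id}, event on {event.date}: {exc}"
            ) from exc
        if match is None:
            continue
        crit, points = match
        if crit.accrual is Accrual.ONCE_PER_PATIENT:
            if crit.name in fired_once:
                continue
            fired_once.add(crit.name)
        else:
            key = (crit.name, event.date)
            if key in seen_dates:
                continue
            seen_dates.add(key)
        contributions.append(
            ScoreContribution(
                date=event.date, criterion=crit.name, points=points, source_event=event
            )
        )

    total = sum((c.points for c in contributions), Decimal(0))
    category = classify(total, config)

    diagnosis_date: Optional[Date] = None
    if category == "diabetes":
        running = Decimal(0)
        for c in contributions:  # already date-ordered
            running += c.points
            if running >= config.diabetes_threshold:
                diagnosis_date = c.date
                break
        assert diagnosis_date is not None

    return PatientScore(
        patient_id=timeline.patient_id,
        contributions=contributions,
        total=total,
        category=category,
        diagnosis_date=diagnosis_date,
    )


@dataclass
class CohortSummary:
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)


def score_cohort(
    cohort: Sequence[PatientTimeline], config: Optional[WeightConfig] = None
) -> tuple[list[PatientScore], CohortSummary]:
    """Score every patient and summarise category counts and fractions."""
    ids = [t.patient_id for t in cohort]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id(s) in cohort: {dupes}")
    scores = [score_patient(t, config) for t in cohort]
    counts = {cat: 0 for cat in CATEGORIES}
    for s in scores:
        counts[s.category] += 1
    n = len(scores)
    fractions = {cat: (counts[cat] / n if n else 0.0) for cat in CATEGORIES}
    summary = CohortSummary(counts=counts, fractions=fractions if n else {})
    if n == 0:
        summary.counts = {}
    return scores, summary


def write_scores(scores: Iterable[PatientScore], path) -> None:
    """Write per-patient results: patient_id, total_points, category,
    diagnosis_date."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "total_points", "category", "diagnosis_date"])
        for s in scores:
            writer.writerow(
                [
                    s.patient_id,
                    str(s.total),
                    s.category,
                    s.diagnosis_date.isoformat() if s.diagnosis_date else "",
                ]
            )


def write_contributions(scores: Iterable[PatientScore], path) -> None:
    """Audit trail: one row per point contribution."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "date", "criterion", "points"])
        for s in scores:
            for c in s.contributions:
                writer.writerow([s.patient_id, c.date.isoformat(), c.criterion, str(c.points)])
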