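"""Two-code claims-based comparator.

The simplest widely used claims rule for diabetes: a patient is identified
when they carry at least two ICD-9 250.xx encounter diagnosis codes on
distinct calendar dates (any care setting), and the diagnosis date is the
date of the second code.  Patients whose only evidence is laboratory or
pharmacy data are invisible to this rule — that gap is what the point-based
model closes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Optional, Sequence

from .model import EventKind, PatientTimeline
from .scoring import _icd9_matches_prefix

__all__ = ["ClaimsResult", "claims_two_code"]


@dataclass(frozen=True)
class ClaimsResult:
    patient_id: str
    identified: bool
    diagnosis_date: Optional[Date]
    n_codes: int


def claims_two_code(
    timeline: PatientTimeline,
    code_prefix: str = "250",
    dedupe_same_date: bool = True,
) -> ClaimsResult:
    """Apply the two-code rule to one patient.

    Qualifying codes are encounter diagnoses matching ``code_prefix`` at the
    ICD-9 category level, in any setting.  With ``dedupe_same_date`` (the
    default) several codes on one calendar date count as a single claim, so
    two codes must fall on distinct dates to identify.
    """
    dates: list[Date] = []
    for ev in sorted(timeline.events, key=lambda e: e.date):
        if ev.kind is not EventKind.ENCOUNTER_DX:
            continue
        if not _icd9_matches_prefix(ev.payload.code, code_prefix):
            continue
        if dedupe_same_date and ev.date in dates:
            continue
        dates.append(ev.date)

    identified = len(dates) >= 2
    return ClaimsResult(
        patient_id=timeline.patient_id,
        identified=identified,
        diagnosis_date=dates[1] if identified else None,
        n_codes=len(dates),
    )


def claims_cohort(cohort: Sequence[PatientTimeline], **kwargs) -> list[ClaimsResult]:
    return [claims_two_code(t, **kwargs) for t in cohort]


def write_claims(results: Iterable[ClaimsResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "identified", "diagnosis_date", "n_codes"])
        for r in results:
            writer.writerow(
                [
                    r.patient_id,
                    str(r.identified).lower(),
                    r.diagnosis_date.isoformat() if r.diagnosis_date else "",
                    r.n_codes,
                ]
            )
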