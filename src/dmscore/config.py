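"""Weight configuration for the point-based case-finding model.

Each criterion assigns a fixed point weight to one kind of chart evidence,
optionally restricted by care setting, with an accrual policy governing how
often it can contribute for one patient:

``per_distinct_date``
    at most one contribution per (criterion, calendar date) — repeated
    qualifying labs or encounter codes on *different* days each add points,
    duplicates within a day do not.

``once_per_patient``
    a single contribution, on the first qualifying date — used for evidence
    whose repetition carries no extra diagnostic information (an active
    medication generates many orders; a problem-list entry persists).

Point weights are exact decimals and the diabetes threshold comparison is
exact: the shipped default weights are all multiples of 0.05 and no
floating-point tolerance is involved anywhere in classification.

The shipped default configuration encodes the published model:

====================  ============================  ======================  ======
criterion             qualifying evidence           settings                points
====================  ============================  ======================  ======
icd9_encounter        ICD-9 250.xx encounter code   inpatient, outpatient   0.75
hba1c                 HbA1c >= 6.5 %                inpatient, outpatient   1.00
fasting_glucose       fasting glucose >= 126 mg/dL  outpatient only         0.50
random_glucose        random glucose >= 200 mg/dL   outpatient only         0.50
ogtt_2h               2-h OGTT >= 200 mg/dL         inpatient, outpatient   0.75
history_dx            250.xx on problem list / PMH  inpatient, outpatient   0.40
diabetes_medication   non-metformin diabetes drug   outpatient only         1.00
metformin             metformin order               outpatient only         0.75
====================  ============================  ======================  ======

Totals of 0, in (0, 1), and >= 1 classify a patient as "none", "possible",
and "diabetes" respectively.  Sites with different documentation quality can
reweight via YAML/JSON (:func:`load_config` / :func:`save_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import CareSetting

__all__ = [
    "Accrual",
    "Criterion",
    "WeightConfig",
    "default_config",
    "load_config",
    "save_config",
]


class Accrual(str, Enum):
    PER_DISTINCT_DATE = "per_distinct_date"
    ONCE_PER_PATIENT = "once_per_patient"


#: Settings meaning "inpatient or outpatient" in the published criteria table.
IN_OR_OUT = frozenset({CareSetting.INPATIENT, CareSetting.OUTPATIENT})
#: "Outpatient only" — excludes inpatient and emergency/urgent care, both of
#: which confound glucose values (stress hyperglycemia) and medication orders
#: (sliding-scale insulin).
OUTPATIENT_ONLY = frozenset({CareSetting.OUTPATIENT})


@dataclass(frozen=True)
class Criterion:
    """One scoring rule: what qualifies, where, and for how many points."""

    name: str
    weight: Decimal
    allowed_settings: frozenset[CareSetting]
    accrual: Accrual
    threshold: Optional[Decimal] = None  # inclusive (>=), for lab criteria
    units: Optional[str] = None
    code_prefix: Optional[str] = None  # ICD-9 category prefix, e.g. "250"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"criterion {self.name}: weight must be >= 0")
        if not self.allowed_settings:
            raise ValueError(f"criterion {self.name}: empty allowed_settings")


@dataclass(frozen=True)
class WeightConfig:
    criteria: tuple[Criterion, ...]
    diabetes_threshold: Decimal = Decimal("1.0")

    def __post_init__(self) -> None:
        if self.diabetes_threshold <= 0:
            raise ValueError("diabetes_threshold must be positive")
        names = [c.name for c in self.criteria]
        if len(names) != len(set(names)):
            raise ValueError("criterion names must be unique")

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_weight(self, name: str, weight: Union[Decimal, str, float]) -> "WeightConfig":
        """A copy of this config with one criterion's weight replaced."""
        w = Decimal(str(weight))
        new = tuple(
            replace(c, weight=w) if c.name == name else c for c in self.criteria
        )
        if new == self.criteria:
            raise KeyError(name)
        return WeightConfig(criteria=new, diabetes_threshold=self.diabetes_threshold)


def default_config() -> WeightConfig:
    """The published default: eight criteria, diagnosis threshold 1 point."""
    d = Decimal
    return WeightConfig(
        criteria=(
            Criterion(
                name="icd9_encounter",
                weight=d("0.75"),
                allowed_settings=IN_OR_OUT,
                accrual=Accrual.PER_DISTINCT_DATE,
                code_prefix="250",
            ),
            Criterion(
                name="hba1c",
                weight=d("1.00"),
                allowed_settings=IN_OR_OUT,
                accrual=Accrual.PER_DISTINCT_DATE,
                threshold=d("6.5"),
                units="%",
            ),
            Criterion(
                name="fasting_glucose",
                weight=d("0.50"),
                allowed_settings=OUTPATIENT_ONLY,
                accrual=Accrual.PER_DISTINCT_DATE,
                threshold=d("126"),
                units="mg/dL",
            ),
            Criterion(
                name="random_glucose",
                weight=d("0.50"),
                allowed_settings=OUTPATIENT_ONLY,
                accrual=Accrual.PER_DISTINCT_DATE,
                threshold=d("200"),
                units="mg/dL",
            ),
            Criterion(
                name="ogtt_2h",
                weight=d("0.75"),
                allowed_settings=IN_OR_OUT,
                accrual=Accrual.PER_DISTINCT_DATE,
                threshold=d("200"),
                units="mg/dL",
            ),
            Criterion(
                name="history_dx",
                weight=d("0.40"),
                allowed_settings=IN_OR_OUT,
                accrual=Accrual.ONCE_PER_PATIENT,
                code_prefix="250",
            ),
            Criterion(
                name="diabetes_medication",
                weight=d("1.00"),
                allowed_settings=OUTPATIENT_ONLY,
                accrual=Accrual.ONCE_PER_PATIENT,
            ),
            Criterion(
                name="metformin",
                weight=d("0.75"),
                allowed_settings=OUTPATIENT_ONLY,
                accrual=Accrual.ONCE_PER_PATIENT,
            ),
        ),
        diabetes_threshold=d("1.0"),
    )


def _criterion_to_dict(c: Criterion) -> dict:
    out: dict = {
        "name": c.name,
        "weight": str(c.weight),
        "allowed_settings": sorted(s.value for s in c.allowed_settings),
        "accrual": c.accrual.value,
    }
    if c.threshold is not None:
        out["threshold"] = str(c.threshold)
        out["units"] = c.units
    if c.code_prefix is not None:
        out["code_prefix"] = c.code_prefix
    return out


def _criterion_from_dict(d: dict) -> Criterion:
    return Criterion(
        name=d["name"],
        weight=Decimal(str(d["weight"])),
        allowed_settings=frozenset(CareSetting(s) for s in d["allowed_settings"]),
        accrual=Accrual(d["accrual"]),
        threshold=Decimal(str(d["threshold"])) if "threshold" in d else None,
        units=d.get("units"),
        code_prefix=d.get("code_prefix"),
    )


def save_config(config: WeightConfig, path: Union[str, Path]) -> None:
    doc = {
        "diabetes_threshold": str(config.diabetes_threshold),
        "criteria": [_criterion_to_dict(c) for c in config.criteria],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: Union[str, Path]) -> WeightConfig:
    """Load a YAML (or JSON — YAML is a superset) weights file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return WeightConfig(
        criteria=tuple(_criterion_from_dict(d) for d in doc["criteria"]),
        diabetes_threshold=Decimal(str(doc["diabetes_threshold"])),
    )
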