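"""Agreement and discrimination statistics for validating the case-finding
model against physician-adjudicated gold labels.

Covers the full validation battery: the 3x3 model-vs-gold agreement table
with Cohen's kappa (unweighted and linear-weighted over the ordered
categories none < possible < diabetes); sensitivity / specificity / PPV /
NPV under both dichotomisations of the "possible" group; an ROC sweep over
point thresholds with trapezoidal area; and diagnosis-date agreement, exact
and within a window (default 92 days, covering any 3-calendar-month span).

PPV and NPV computed here are conditional on the supplied cohort's
prevalence; on a case-enriched validation sample they are inflated relative
to the source population, and :func:`validate` flags this in its report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional, Sequence

import numpy as np

from .claims import ClaimsResult
from .model import GoldLabel
from .scoring import CATEGORIES, PatientScore

__all__ = [
    "ConfusionMatrix2x2",
    "binary_metrics",
    "collapse",
    "agreement_table",
    "cohen_kappa",
    "RocCurve",
    "roc_over_thresholds",
    "DateAgreement",
    "date_agreement",
    "ValidationReport",
    "validate",
]


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> Optional[float]:
    """A proportion, or ``None`` when the denominator is empty (undefined,
    never reported as 0)."""
    return num / den if den > 0 else None


def binary_metrics(cm: ConfusionMatrix2x2) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV and NPV from a 2x2 table."""
    return {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
    }


def collapse(labels: Sequence[str], mode: str) -> list[bool]:
    """Dichotomise three-way labels.

    ``possible_as_negative`` folds "possible" in with "none" (the primary
    analysis); ``possible_as_positive`` folds it in with "diabetes" (the
    sensitivity analysis).  Returns True for positive.
    """
    if mode == "possible_as_negative":
        positive = {"diabetes"}
    elif mode == "possible_as_positive":
        positive = {"diabetes", "possible"}
    else:
        raise ValueError(f"unknown collapse mode {mode!r}")
    out = []
    for lab in labels:
        if lab not in CATEGORIES:
            raise ValueError(f"unknown label {lab!r}")
        out.append(lab in positive)
    return out


def confusion_2x2(model_pos: Sequence[bool], gold_pos: Sequence[bool]) -> ConfusionMatrix2x2:
    if len(model_pos) != len(gold_pos):
        raise ValueError("length mismatch")
    tp = sum(1 for m, g in zip(model_pos, gold_pos) if m and g)
    fp = sum(1 for m, g in zip(model_pos, gold_pos) if m and not g)
    fn = sum(1 for m, g in zip(model_pos, gold_pos) if not m and g)
    tn = sum(1 for m, g in zip(model_pos, gold_pos) if not m and not g)
    return ConfusionMatrix2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def agreement_table(
    model: Sequence[str], gold: Sequence[str], categories: Sequence[str] = CATEGORIES
) -> np.ndarray:
    """Square contingency table, rows = model, cols = gold, over the ordered
    categories."""
    if len(model) != len(gold):
        raise ValueError("length mismatch")
    idx = {c: i for i, c in enumerate(categories)}
    table = np.zeros((len(categories), len(categories)), dtype=int)
    for m, g in zip(model, gold):
        table[idx[m], idx[g]] += 1
    return table


def cohen_kappa(table: np.ndarray, weights: str = "unweighted") -> Optional[float]:
    """Cohen's kappa from a square contingency table.

    ``weights="linear"`` uses disagreement weights |i-j|/(k-1) over the
    ordered categories, so a model/gold pair one category apart is a partial
    disagreement.  On a 2x2 table linear and unweighted kappa coincide.
    Returns ``None`` when chance agreement is 1 (degenerate marginals make
    kappa undefined).
    """
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    if table.shape != (k, k):
        raise ValueError("table must be square")
    n = table.sum()
    if n <= 0:
        raise ValueError("table total must be positive")

    i, j = np.indices((k, k))
    if weights == "unweighted":
        w = (i != j).astype(float)
    elif weights == "linear":
        w = np.abs(i - j) / (k - 1) if k > 1 else np.zeros((1, 1))
    else:
        raise ValueError(f"unknown weights {weights!r}")

    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    disagree_obs = (w * p).sum()
    disagree_exp = (w * expected).sum()
    if math.isclose(disagree_exp, 0.0, abs_tol=1e-15):
        return None
    return 1.0 - disagree_obs / disagree_exp


@dataclass
class RocCurve:
    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float


def roc_over_thresholds(
    scores: Sequence[tuple[float, bool]],
    thresholds: Optional[Sequence[float]] = None,
) -> RocCurve:
    """Sweep point thresholds over (total, gold-positive) pairs.

    At each threshold t the model calls positive iff total >= t.  The area
    is the trapezoidal rule over the resulting (1-specificity, sensitivity)
    points augmented with (0,0) and (1,1).  By default the grid is every
    distinct observed total.
    """
    totals = np.array([float(s) for s, _ in scores])
    gold = np.array([bool(g) for _, g in scores])
    if gold.all() or not gold.any():
        raise ValueError("ROC requires at least one positive and one negative gold label")
    if thresholds is None:
        thresholds = sorted(set(totals))

    pts = []
    for t in thresholds:
        pred = totals >= t
        tp = int((pred & gold).sum())
        fp = int((pred & ~gold).sum())
        fn = int((~pred & gold).sum())
        tn = int((~pred & ~gold).sum())
        pts.append((float(t), tp / (tp + fn), tn / (tn + fp)))

    # monotone staircase in (1-specificity, sensitivity), closed at both ends
    pairs = sorted([(1.0 - spec, sens) for _, sens, spec in pts] + [(0.0, 0.0), (1.0, 1.0)])
    xs = np.array([x for x, _ in pairs])
    ys = np.array([y for _, y in pairs])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=pts, auc=auc)


@dataclass
class DateAgreement:
    n_pairs: int
    n_exact: int
    n_within_window: int
    window_days: int
    mode: str  # "symmetric" or "model_late"
    delays: list[int] = field(default_factory=list)  # model - gold, days

    @property
    def exact_fraction(self) -> Optional[float]:
        return _ratio(self.n_exact, self.n_pairs)

    @property
    def within_window_fraction(self) -> Optional[float]:
        return _ratio(self.n_within_window, self.n_pairs)


def date_agreement(
    pairs: Sequence[tuple[Date, Date]],
    window_days: int = 92,
    mode: str = "symmetric",
) -> DateAgreement:
    """Diagnosis-date agreement over (model_date, gold_date) pairs.

    ``symmetric`` counts |model - gold| <= window as agreement;
    ``model_late`` counts 0 <= model - gold <= window (the model may trail
    the chart date by up to the window but never anticipate it).
    """
    if mode not in ("symmetric", "model_late"):
        raise ValueError(f"unknown window mode {mode!r}")
    delays = [(m - g).days for m, g in pairs]
    n_exact = sum(1 for d in delays if d == 0)
    if mode == "symmetric":
        n_within = sum(1 for d in delays if abs(d) <= window_days)
    else:
        n_within = sum(1 for d in delays if 0 <= d <= window_days)
    return DateAgreement(
        n_pairs=len(delays),
        n_exact=n_exact,
        n_within_window=n_within,
        window_days=window_days,
        mode=mode,
        delays=delays,
    )


@dataclass
class ValidationReport:
    n: int
    table: np.ndarray  # 3x3, rows = model, cols = gold
    kappa_unweighted: Optional[float]
    kappa_linear: Optional[float]
    metrics_possible_as_negative: dict[str, Optional[float]]
    metrics_possible_as_positive: dict[str, Optional[float]]
    roc: Optional[RocCurve]
    date_agreement_model: Optional[DateAgreement]
    date_agreement_model_one_sided: Optional[DateAgreement]
    date_agreement_claims: Optional[DateAgreement]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def da(d: Optional[DateAgreement]):
            if d is None:
                return None
            return {
                "n_pairs": d.n_pairs,
                "n_exact": d.n_exact,
                "n_within_window": d.n_within_window,
                "window_days": d.window_days,
                "mode": d.mode,
                "exact_fraction": d.exact_fraction,
                "within_window_fraction": d.within_window_fraction,
            }

        return {
            "n": self.n,
            "agreement_table": {
                "categories": list(CATEGORIES),
                "rows_model_cols_gold": self.table.tolist(),
            },
            "kappa_unweighted": self.kappa_unweighted,
            "kappa_linear": self.kappa_linear,
            "metrics_possible_as_negative": self.metrics_possible_as_negative,
            "metrics_possible_as_positive": self.metrics_possible_as_positive,
            "roc": None
            if self.roc is None
            else {
                "points": [
                    {"threshold": t, "sensitivity": se, "specificity": sp}
                    for t, se, sp in self.roc.points
                ],
                "auc": self.roc.auc,
            },
            "date_agreement_model": da(self.date_agreement_model),
            "date_agreement_model_one_sided": da(self.date_agreement_model_one_sided),
            "date_agreement_claims": da(self.date_agreement_claims),
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def validate(
    scores: Sequence[PatientScore],
    gold: Sequence[GoldLabel],
    claims: Optional[Sequence[ClaimsResult]] = None,
    window_days: int = 92,
) -> ValidationReport:
    """Full validation of model output against gold labels.

    Patient ids must align one-to-one; the pairing is by id, not order.
    The ROC uses the primary dichotomisation of gold (possible folded into
    negative).  Date agreement is restricted to patients called diabetic by
    both model (or claims comparator) and gold.
    """
    gold_by_id = {g.patient_id: g for g in gold}
    score_ids = {s.patient_id for s in scores}
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate patient_id in gold labels")
    missing = sorted(score_ids - set(gold_by_id))
    extra = sorted(set(gold_by_id) - score_ids)
    if missing or extra:
        raise ValueError(
            f"patient_id mismatch between scores and gold; "
            f"no gold label for {missing}; no score for {extra}"
        )

    model_labels = [s.category for s in scores]
    gold_labels = [gold_by_id[s.patient_id].category for s in scores]

    table = agreement_table(model_labels, gold_labels)
    kappa_u = cohen_kappa(table, "unweighted")
    kappa_l = cohen_kappa(table, "linear")

    reports = {}
    for mode in ("possible_as_negative", "possible_as_positive"):
        cm = confusion_2x2(collapse(model_labels, mode), collapse(gold_labels, mode))
        reports[mode] = binary_metrics(cm)

    gold_pos = collapse(gold_labels, "possible_as_negative")
    roc: Optional[RocCurve] = None
    if any(gold_pos) and not all(gold_pos):
        roc = roc_over_thresholds(
            [(float(s.total), g) for s, g in zip(scores, gold_pos)]
        )

    pairs = [
        (s.diagnosis_date, gold_by_id[s.patient_id].date)
        for s in scores
        if s.diagnosis_date is not None and gold_by_id[s.patient_id].date is not None
    ]
    da_model = date_agreement(pairs, window_days, "symmetric") if pairs else None
    da_model_one = date_agreement(pairs, window_days, "model_late") if pairs else None

    da_claims = None
    if claims is not None:
        cpairs = [
            (c.diagnosis_date, gold_by_id[c.patient_id].date)
            for c in claims
            if c.patient_id in gold_by_id
            and c.diagnosis_date is not None
            and gold_by_id[c.patient_id].date is not None
        ]
        da_claims = date_agreement(cpairs, window_days, "symmetric") if cpairs else None

    notes = [
        "PPV and NPV are prevalence-dependent; on a case-enriched validation "
        "sample they are inflated relative to the source population."
    ]
    return ValidationReport(
        n=len(scores),
        table=table,
        kappa_unweighted=kappa_u,
        kappa_linear=kappa_l,
        metrics_possible_as_negative=reports["possible_as_negative"],
        metrics_possible_as_positive=reports["possible_as_positive"],
        roc=roc,
        date_agreement_model=da_model,
        date_agreement_model_one_sided=da_model_one,
        date_agreement_claims=da_claims,
        notes=notes,
    )
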