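"""Validation statistics: binary metrics, label collapsing, Cohen's kappa
(unweighted and linear), ROC threshold sweeps, and date agreement — each
cross-checked against an independent route (hand arithmetic, scikit-learn,
or pairwise Mann-Whitney counting)."""

from datetime import date as Date, timedelta
from decimal import Decimal

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from dmscore.metrics import (
    ConfusionMatrix2x2,
    agreement_table,
    binary_metrics,
    cohen_kappa,
    collapse,
    confusion_2x2,
    date_agreement,
    roc_over_thresholds,
    validate,
)
from dmscore.model import GoldLabel
from dmscore.scoring import PatientScore


def make_score(pid, total, category, date=None):
    return PatientScore(patient_id=pid, contributions=[], total=Decimal(str(total)),
                        category=category, diagnosis_date=date)


class TestBinaryMetrics:
    def test_symmetric_case(self):
        m = binary_metrics(ConfusionMatrix2x2(tp=9, fp=1, fn=1, tn=9))
        assert m == {"sensitivity": 0.9, "specificity": 0.9, "ppv": 0.9, "npv": 0.9}

    def test_perfect_classifier(self):
        m = binary_metrics(ConfusionMatrix2x2(tp=5, fp=0, fn=0, tn=5))
        assert all(v == 1.0 for v in m.values())

    def test_direct_arithmetic(self):
        m = binary_metrics(ConfusionMatrix2x2(tp=97, fp=10, fn=3, tn=90))
        assert m["sensitivity"] == pytest.approx(0.97)
        assert m["specificity"] == pytest.approx(0.90)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = binary_metrics(ConfusionMatrix2x2(tp=0, fp=0, fn=0, tn=10))
        assert m["sensitivity"] is None and m["ppv"] is None
        assert m["specificity"] == 1.0

    def test_swapping_labels_swaps_sens_spec_and_ppv_npv(self):
        cm = ConfusionMatrix2x2(tp=40, fp=7, fn=3, tn=50)
        swapped = ConfusionMatrix2x2(tp=cm.tn, fp=cm.fn, fn=cm.fp, tn=cm.tp)
        m, ms = binary_metrics(cm), binary_metrics(swapped)
        assert ms["sensitivity"] == m["specificity"]
        assert ms["specificity"] == m["sensitivity"]
        assert ms["ppv"] == m["npv"]
        assert ms["npv"] == m["ppv"]


class TestCollapse:
    def test_possible_as_negative(self):
        assert collapse(["possible", "diabetes", "none"], "possible_as_negative") == [False, True, False]

    def test_possible_as_positive(self):
        assert collapse(["possible", "diabetes", "none"], "possible_as_positive") == [True, True, False]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            collapse(["maybe"], "possible_as_negative")


class TestCohenKappa:
    def test_diagonal_table_is_one(self):
        table = np.diag([5, 3, 7])
        assert cohen_kappa(table, "unweighted") == pytest.approx(1.0)
        assert cohen_kappa(table, "linear") == pytest.approx(1.0)

    def test_chance_level_agreement_is_zero(self):
        # independent marginals: observed == expected agreement
        table = np.outer([2, 2], [3, 3])
        assert cohen_kappa(table, "unweighted") == pytest.approx(0.0)

    def test_degenerate_marginals_undefined(self):
        table = np.array([[10, 0, 0], [0, 0, 0], [0, 0, 0]])
        assert cohen_kappa(table, "unweighted") is None

    @pytest.mark.parametrize("weights", ["unweighted", "linear"])
    def test_matches_sklearn_on_random_tables(self, weights):
        """Independent cross-check: expand each random contingency table
        into paired label vectors and compare with scikit-learn."""
        rng = np.random.default_rng(99)
        sk_weights = None if weights == "unweighted" else "linear"
        n_checked = 0
        while n_checked < 500:
            k = int(rng.integers(2, 5))
            table = rng.integers(0, 6, size=(k, k))
            if table.sum() == 0:
                continue
            y1, y2 = [], []
            for i in range(k):
                for j in range(k):
                    y1 += [i] * table[i, j]
                    y2 += [j] * table[i, j]
            ours = cohen_kappa(table, weights)
            theirs = cohen_kappa_score(y1, y2, labels=list(range(k)), weights=sk_weights)
            if ours is None:
                assert np.isnan(theirs) or theirs == 0.0
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)
            n_checked += 1

    def test_linear_equals_unweighted_on_2x2(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            table = rng.integers(0, 10, size=(2, 2))
            if table.sum() == 0:
                continue
            u = cohen_kappa(table, "unweighted")
            l = cohen_kappa(table, "linear")
            assert (u is None and l is None) or u == pytest.approx(l, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        scores = [(1.0, True)] * 5 + [(0.0, False)] * 5
        roc = roc_over_thresholds(scores, thresholds=[0.5, 1.0])
        assert roc.auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        scores = [(0.75, True)] * 5 + [(0.75, False)] * 5
        assert roc_over_thresholds(scores).auc == pytest.approx(0.5)

    def test_all_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_over_thresholds([(1.0, True), (0.5, True)])

    def test_six_patient_exhaustive_enumeration(self):
        """Every threshold's confusion matrix, checked by hand-enumerating
        predictions."""
        data = [(0.0, False), (0.4, False), (0.75, False), (0.75, True), (1.0, True), (1.5, True)]
        roc = roc_over_thresholds(data)
        for t, sens, spec in roc.points:
            tp = sum(1 for s, g in data if g and s >= t)
            fn = sum(1 for s, g in data if g and s < t)
            tn = sum(1 for s, g in data if not g and s < t)
            fp = sum(1 for s, g in data if not g and s >= t)
            assert sens == pytest.approx(tp / (tp + fn))
            assert spec == pytest.approx(tn / (tn + fp))

    def test_auc_equals_mann_whitney_probability(self):
        """Trapezoidal area over the full threshold sweep equals the
        tie-corrected pairwise probability P(score_pos > score_neg), also
        computable via scikit-learn's rank-based AUC."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            totals = rng.choice([0.0, 0.4, 0.5, 0.75, 1.0, 1.15, 1.5, 2.0], size=n)
            gold = rng.random(n) < 0.5
            if gold.all() or not gold.any():
                continue
            pairs = list(zip(totals.tolist(), gold.tolist()))
            auc = roc_over_thresholds(pairs).auc
            # brute-force pairwise count
            pos = totals[gold]
            neg = totals[~gold]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(gold, totals), abs=1e-12)


class TestDateAgreement:
    def test_all_exact(self):
        d = Date(2009, 5, 1)
        rep = date_agreement([(d, d)] * 4)
        assert rep.n_exact == rep.n_pairs == rep.n_within_window == 4

    def test_within_window_delay(self):
        rep = date_agreement([(Date(2009, 4, 1), Date(2009, 1, 15))], window_days=92)
        assert rep.delays == [76]
        assert rep.n_within_window == 1 and rep.n_exact == 0

    def test_late_beyond_window_disagrees(self):
        g = Date(2009, 1, 1)
        rep = date_agreement([(g + timedelta(days=200), g)], window_days=92)
        assert rep.n_within_window == 0

    def test_one_sided_mode_rejects_early_model_dates(self):
        g = Date(2009, 6, 1)
        pairs = [(g - timedelta(days=30), g)]
        assert date_agreement(pairs, mode="symmetric").n_within_window == 1
        assert date_agreement(pairs, mode="model_late").n_within_window == 0

    def test_empty_pairs_is_empty_report(self):
        rep = date_agreement([])
        assert rep.n_pairs == 0 and rep.exact_fraction is None

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        base = Date(2009, 1, 1)
        pairs = [
            (base + timedelta(days=int(rng.integers(0, 400))),
             base + timedelta(days=int(rng.integers(0, 400))))
            for _ in range(50)
        ]
        shifted = [(m + timedelta(days=123), g + timedelta(days=123)) for m, g in pairs]
        a, b = date_agreement(pairs), date_agreement(shifted)
        assert (a.n_exact, a.n_within_window, a.delays) == (b.n_exact, b.n_within_window, b.delays)


class TestValidate:
    def _cohort(self, n=20):
        scores, gold = [], []
        d = Date(2009, 7, 1)
        for i in range(n):
            pid = f"P{i}"
            cat = ["none", "possible", "diabetes"][i % 3]
            date = d if cat == "diabetes" else None
            scores.append(make_score(pid, {"none": 0, "possible": 0.75, "diabetes": 1.5}[cat], cat, date))
            gold.append(GoldLabel(pid, cat, date))
        return scores, gold

    def test_perfect_agreement(self):
        scores, gold = self._cohort()
        rep = validate(scores, gold)
        assert rep.kappa_unweighted == pytest.approx(1.0)
        assert rep.kappa_linear == pytest.approx(1.0)
        assert all(v == 1.0 for v in rep.metrics_possible_as_negative.values())
        assert rep.date_agreement_model.n_exact == rep.date_agreement_model.n_pairs

    def test_systematic_flip_gives_negative_kappa(self):
        """Swapping every gold none<->diabetes label on a two-category
        cohort turns perfect agreement into systematic disagreement."""
        d = Date(2009, 7, 1)
        scores, flipped = [], []
        for i in range(20):
            pid = f"P{i}"
            if i % 2 == 0:
                scores.append(make_score(pid, 1.5, "diabetes", d))
                flipped.append(GoldLabel(pid, "none"))
            else:
                scores.append(make_score(pid, 0.0, "none"))
                flipped.append(GoldLabel(pid, "diabetes", d))
        rep = validate(scores, flipped)
        assert rep.kappa_unweighted < 0

    def test_mismatched_ids_listed(self):
        scores, gold = self._cohort(6)
        gold[0] = GoldLabel("QX", gold[0].category, gold[0].date)
        with pytest.raises(ValueError, match="QX"):
            validate(scores, gold)

    def test_hand_planted_errors_match_hand_computation(self):
        """A 30-patient set with known misclassifications reproduces the
        hand-computed confusion table and binary metrics."""
        scores, gold = [], []
        d = Date(2009, 7, 1)
        # 10 true positives, 2 false negatives (model possible, gold diabetes),
        # 15 true negatives, 3 false positives (model diabetes, gold none)
        for i in range(10):
            scores.append(make_score(f"TP{i}", 1.5, "diabetes", d))
            gold.append(GoldLabel(f"TP{i}", "diabetes", d))
        for i in range(2):
            scores.append(make_score(f"FN{i}", 0.75, "possible"))
            gold.append(GoldLabel(f"FN{i}", "diabetes", d))
        for i in range(15):
            scores.append(make_score(f"TN{i}", 0.0, "none"))
            gold.append(GoldLabel(f"TN{i}", "none"))
        for i in range(3):
            scores.append(make_score(f"FP{i}", 1.0, "diabetes", d))
            gold.append(GoldLabel(f"FP{i}", "none"))
        rep = validate(scores, gold)
        m = rep.metrics_possible_as_negative
        assert m["sensitivity"] == pytest.approx(10 / 12)
        assert m["specificity"] == pytest.approx(15 / 18)
        assert m["ppv"] == pytest.approx(10 / 13)
        assert m["npv"] == pytest.approx(15 / 17)
        # 3x3 table rows=model, cols=gold over (none, possible, diabetes)
        expected = np.array([[15, 0, 0], [0, 0, 2], [3, 0, 10]])
        assert (rep.table == expected).all()
        assert rep.roc is not None and 0.0 <= rep.roc.auc <= 1.0
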