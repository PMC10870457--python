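"""Metric formulas against brute-force oracles; ROC/AUC equivalences."""

import math

import numpy as np
import pytest

from kcrnet.evaluation import (
    ConfusionCounts,
    MetricsReport,
    aggregate,
    confusion,
    evaluate_scores,
    metrics,
    roc_auc,
)


def brute_force_metrics(tp, fp, tn, fn):
    """Independent implementation straight from the definitions."""
    out = {}
    out["Sn"] = tp / (tp + fn) if tp + fn else None
    out["Sp"] = tn / (tn + fp) if tn + fp else None
    total = tp + fp + tn + fn
    out["ACC"] = (tp + tn) / total if total else None
    out["F1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["MCC"] = (tp * tn - fp * fn) / math.sqrt(den) if den else None
    return out


def pairwise_auc(labels, scores):
    """O(n^2) tie-aware ranking probability."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_simple_tally(self):
        c = confusion([1, 0], [0.9, 0.1])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_exact_half_goes_negative(self):
        c = confusion([1, 0], [0.5, 0.5])
        assert c.TP == 0 and c.FN == 1 and c.TN == 1

    def test_matches_loop_oracle(self, rng):
        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        c = confusion(labels, scores)
        tp = sum(1 for l, s in zip(labels, scores) if l == 1 and s > 0.5)
        fp = sum(1 for l, s in zip(labels, scores) if l == 0 and s > 0.5)
        fn = sum(1 for l, s in zip(labels, scores) if l == 1 and s <= 0.5)
        tn = sum(1 for l, s in zip(labels, scores) if l == 0 and s <= 0.5)
        assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1], [0.5, 0.5])
        with pytest.raises(ValueError, match="empty"):
            confusion([], [])
        with pytest.raises(ValueError, match="negative"):
            ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert all(m[k] == 1.0 for k in ("Sn", "Sp", "ACC", "F1", "MCC"))

    def test_random_like_mcc_zero(self):
        m = metrics(ConfusionCounts(TP=25, FN=25, TN=40, FP=40))
        assert m["MCC"] == pytest.approx(0.0)

    def test_worked_example(self):
        """TP=70 FN=30 TN=80 FP=20: direct arithmetic on the definitions."""
        m = metrics(ConfusionCounts(TP=70, FP=20, TN=80, FN=30))
        assert m["Sn"] == pytest.approx(0.7)
        assert m["Sp"] == pytest.approx(0.8)
        assert m["ACC"] == pytest.approx(0.75)
        assert m["F1"] == pytest.approx(140 / 190)
        assert m["MCC"] == pytest.approx(5000 / math.sqrt(90 * 100 * 100 * 110))

    def test_undefined_marked_not_zero(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=10, FN=0))
        assert m["Sn"] is None and m["MCC"] is None
        assert m["Sp"] == 1.0

    def test_against_brute_force_on_random_tables(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, 4))
            got = metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            expected = brute_force_metrics(tp, fp, tn, fn)
            for k in expected:
                if expected[k] is None:
                    assert got[k] is None
                else:
                    assert got[k] == pytest.approx(expected[k], abs=0)

    def test_acc_identity(self, rng):
        """ACC = (Sn*P + Sp*N) / (P+N) whenever both are defined."""
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 50, 4))
            m = metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            P, N = tp + fn, tn + fp
            assert m["ACC"] == pytest.approx((m["Sn"] * P + m["Sp"] * N) / (P + N))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert curve.auc == 1.0

    def test_all_tied_scores(self):
        curve = roc_auc([0, 1, 0, 1], [0.5] * 4)
        assert curve.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60).round(1)  # force ties
        curve = roc_auc(labels, scores)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    def test_trapezoid_equals_pairwise_oracle(self, rng):
        for trial in range(20):
            n = 50
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = rng.random(n).round(2 if trial % 2 else 6)
            curve = roc_auc(labels, scores)
            assert curve.auc == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        scores = rng.random(80)
        a1 = roc_auc(labels, scores).auc
        a2 = roc_auc(labels, scores**3).auc  # strictly monotone on [0,1]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        """Independent cross-check against an established implementation."""
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200).round(2)
        assert roc_auc(labels, scores).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_undefined(self):
        with pytest.warns(UserWarning, match="one class"):
            assert roc_auc([1, 1], [0.2, 0.9]).auc is None


class TestAggregate:
    def _report(self, **kw):
        return MetricsReport(**{**dict(Sn=0.5, Sp=0.5, ACC=0.5, F1=0.5, MCC=0.0, AUC=0.5), **kw})

    def test_identical_reports_zero_std(self):
        agg = aggregate([self._report(), self._report()])
        assert agg.AUC == 0.5 and agg.std["AUC"] == 0.0

    def test_two_values_closed_form(self):
        """AUC 0.8 and 0.9 -> mean 0.85, sample std |0.8-0.9|/sqrt(2)."""
        agg = aggregate([self._report(AUC=0.8), self._report(AUC=0.9)])
        assert agg.AUC == pytest.approx(0.85)
        assert agg.std["AUC"] == pytest.approx(0.1 / math.sqrt(2))

    def test_single_report_std_undefined(self):
        agg = aggregate([self._report()])
        assert agg.std["AUC"] is None

    def test_undefined_entries_excluded_pairwise(self):
        agg = aggregate([self._report(Sn=None, AUC=0.8), self._report(AUC=0.9)])
        assert agg.Sn == 0.5  # only the defined value contributes
        assert agg.AUC == pytest.approx(0.85)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            aggregate([])


def test_evaluate_scores_combines_suite(rng):
    labels = rng.integers(0, 2, 100)
    labels[:2] = [0, 1]
    scores = rng.random(100)
    rep = evaluate_scores(labels, scores)
    c = confusion(labels, scores)
    assert rep.Sn == metrics(c)["Sn"]
    assert rep.AUC == roc_auc(labels, scores).auc
    assert rep.n == 100
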