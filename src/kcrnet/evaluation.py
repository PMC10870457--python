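"""Binary-classification metrics: Sn, Sp, ACC, F1, MCC, ROC/AUC.

All threshold metrics use the fixed decision rule "predicted positive iff
score > threshold" (strict inequality, default 0.5, so a score of exactly
0.5 is negative):

    Sn  = TP / (TP + FN)              Sp  = TN / (TN + FP)
    ACC = (TP + TN) / n               F1  = 2 TP / (2 TP + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero denominator makes the metric undefined; undefined values are
reported as ``None`` (never silently 0) and excluded metric-wise from
aggregation.  AUC is computed two ways — trapezoidal integration of the
tie-grouped ROC sweep and the tie-aware pairwise-ranking probability — and
the two must agree to 1e-12; the ROC sweep is returned for plotting.
Aggregation across folds/runs reports the arithmetic mean and the sample
(n-1) standard deviation per metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_scores",
    "aggregate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("Sn", "Sp", "ACC", "F1", "MCC", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """The six-metric suite; None marks an undefined (0/0) value."""

    Sn: float | None = None
    Sp: float | None = None
    ACC: float | None = None
    F1: float | None = None
    MCC: float | None = None
    AUC: float | None = None
    threshold: float = 0.5
    std: dict[str, float | None] = field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["threshold"] = self.threshold
        d["n"] = self.n
        if self.std:
            d["std"] = dict(self.std)
        return d


@dataclass
class RocCurve:
    """(FPR, TPR) points from a threshold sweep (one point per unique score)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _check_inputs(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(f"labels and scores differ in length: {labels.shape} vs {scores.shape}")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return labels.astype(np.int64), scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/TN/FN under the strict "score > threshold" rule."""
    labels, scores = _check_inputs(labels, scores)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sn, Sp, ACC, F1, MCC from a confusion table (None where undefined)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return {
        "Sn": _ratio(tp, tp + fn),
        "Sp": _ratio(tn, tn + fp),
        "ACC": _ratio(tp + tn, counts.total),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn),
        "MCC": None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
    }


def roc_auc(labels, scores) -> RocCurve:
    """ROC sweep and AUC; single-class input yields AUC None with a warning.

    The sweep visits thresholds at each unique score (descending), grouping
    ties.  AUC is the trapezoidal area and is cross-checked internally
    against the tie-aware pairwise-ranking probability
    (#concordant + 0.5 #tied) / (n_pos * n_neg); disagreement beyond 1e-12
    is a bug and raises.
    """
    labels, scores = _check_inputs(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("ROC undefined: only one class present", stacklevel=2)
        return RocCurve(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, -np.inf]),
            auc=None,
        )
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # group tied scores: cumulative counts at the last index of each group
    distinct = np.r_[np.diff(s) != 0, True]
    tp_cum = np.cumsum(y)[distinct]
    fp_cum = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc_trap = float(np.trapezoid(tpr, fpr))
    # tie-aware pairwise-ranking probability via rank sums
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties
    auc_rank = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if abs(auc_trap - auc_rank) > 1e-12:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} and pairwise AUC {auc_rank!r} disagree"
        )
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_trap)


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full six-metric report for a set of scored samples."""
    counts = confusion(labels, scores, threshold)
    m = metrics(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = roc_auc(labels, scores)
    return MetricsReport(
        Sn=m["Sn"],
        Sp=m["Sp"],
        ACC=m["ACC"],
        F1=m["F1"],
        MCC=m["MCC"],
        AUC=curve.auc,
        threshold=threshold,
        n=len(np.asarray(labels)),
    )


def aggregate(reports: list[MetricsReport]) -> MetricsReport:
    """Mean and sample (n-1) std per metric; undefined entries excluded pairwise.

    With a single defined value the std is undefined (None).
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out = MetricsReport(threshold=reports[0].threshold, n=sum(r.n for r in reports))
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            setattr(out, name, None)
            out.std[name] = None
            continue
        arr = np.asarray(vals, dtype=np.float64)
        setattr(out, name, float(arr.mean()))
        out.std[name] = float(arr.std(ddof=1)) if arr.size > 1 else None
    return out
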