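"""Classical-learner baselines: random forest, AdaBoost, gradient boosting.

Each of the three learners is trained on each of the five fixed feature
encodings (one-hot, composition, grouped composition, physicochemical
indices, BLOSUM62 rows; word IDs are excluded — they are only meaningful
through a trainable embedding).  Matrix encodings are row-flattened into
feature vectors; the learners run through the same split/CV/metric
machinery as the networks.  Hyperparameters are library defaults with a
fixed seed; no imbalance correction is applied to the classical learners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import DatasetSplit, kfold_partition
from .encoders import encode_windows
from .evaluation import MetricsReport, aggregate, evaluate_scores
from .sequence_io import Peptide

__all__ = [
    "ClassicalSpec",
    "CLASSICAL_LEARNERS",
    "CLASSICAL_ENCODINGS",
    "flatten_features",
    "make_learner",
    "run_classical",
    "run_all_classical",
]

CLASSICAL_LEARNERS = ("random_forest", "ada_boost", "gradient_boosted_trees")
CLASSICAL_ENCODINGS = ("be", "aac", "egaac", "aaindex", "blosum62")

_FEATURE_DIMS = {"be": 609, "aac": 21, "egaac": 5, "aaindex": 841, "blosum62": 609}


@dataclass(frozen=True)
class ClassicalSpec:
    learner: str
    encoding: str
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.learner not in CLASSICAL_LEARNERS:
            raise ValueError(
                f"learner must be one of {CLASSICAL_LEARNERS}, got {self.learner!r}"
            )
        if self.encoding not in CLASSICAL_ENCODINGS:
            raise ValueError(
                f"encoding must be one of {CLASSICAL_ENCODINGS}, got {self.encoding!r}"
            )


def flatten_features(samples: list[Peptide], encoding: str) -> tuple[np.ndarray, np.ndarray]:
    """Feature table (n, d) and labels; matrix encodings are row-flattened."""
    if encoding not in CLASSICAL_ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}; choose from {CLASSICAL_ENCODINGS}")
    X = encode_windows([s.window for s in samples], encoding)
    X = X.reshape(len(samples), -1)
    assert X.shape[1] == _FEATURE_DIMS[encoding]
    y = np.asarray([s.label for s in samples], dtype=np.int64)
    return X, y


def make_learner(spec: ClassicalSpec):
    """Instantiate the scikit-learn / LightGBM estimator for a spec."""
    if spec.learner == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=spec.seed, **spec.hyperparameters)
    if spec.learner == "ada_boost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(random_state=spec.seed, **spec.hyperparameters)
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=spec.seed, verbose=-1, **spec.hyperparameters)


def run_classical(
    spec: ClassicalSpec, split: DatasetSplit, k: int = 5
) -> dict[str, MetricsReport]:
    """Cross-validation on the training side plus one independent test.

    Returns {"cv": mean +/- std across folds, "test": independent-test report}.
    """
    X_tr, y_tr = flatten_features(split.train, spec.encoding)
    X_te, y_te = flatten_features(split.test, spec.encoding)
    folds = kfold_partition(split.train, k=k, seed=spec.seed, stratify_by_label=True)
    with warnings.catch_warnings():
        # plain ndarray features carry no column names; silence the
        # estimator-side feature-name bookkeeping warning
        warnings.filterwarnings("ignore", message=".*feature names.*")
        fold_reports = []
        for j in range(folds.k):
            va = folds.fold_indices(j)
            tr = np.setdiff1d(np.arange(len(y_tr)), va)
            est = make_learner(spec)
            est.fit(X_tr[tr], y_tr[tr])
            scores = est.predict_proba(X_tr[va])[:, 1]
            fold_reports.append(evaluate_scores(y_tr[va], scores))
        est = make_learner(spec)
        est.fit(X_tr, y_tr)
        test_report = evaluate_scores(y_te, est.predict_proba(X_te)[:, 1])
    return {"cv": aggregate(fold_reports), "test": test_report}


def run_all_classical(
    split: DatasetSplit,
    k: int = 5,
    seed: int = 0,
    learners=CLASSICAL_LEARNERS,
    encodings=CLASSICAL_ENCODINGS,
) -> pd.DataFrame:
    """Every (learner, encoding) pair in long format.

    Columns: learner, encoding, phase (cv/test), metric, mean, std; failed
    combinations appear with status 'failed' instead of being dropped.
    """
    rows = []
    for learner in learners:
        for encoding in encodings:
            spec = ClassicalSpec(learner=learner, encoding=encoding, seed=seed)
            try:
                res = run_classical(spec, split, k=k)
            except Exception as e:  # record, never silently drop
                rows.append(
                    dict(learner=learner, encoding=encoding, phase="error",
                         metric="status", mean=None, std=None, note=str(e))
                )
                continue
            for phase, rep in res.items():
                for metric in ("Sn", "Sp", "ACC", "F1", "MCC", "AUC"):
                    rows.append(
                        dict(
                            learner=learner,
                            encoding=encoding,
                            phase=phase,
                            metric=metric,
                            mean=getattr(rep, metric),
                            std=rep.std.get(metric) if rep.std else None,
                            note="",
                        )
                    )
    return pd.DataFrame(rows)
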