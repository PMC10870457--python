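"""Training loops and evaluation protocols for the networks.

Optimization follows the published protocol: Adam at learning rate 0.001,
batch size 256, focal loss (alpha = 0.7, gamma = 1), 50 epochs by default
(tests and examples use far fewer).  Every source of randomness is derived
from the run seed: parameter init and dropout masks from the model seed,
the epoch-e shuffle from (seed, e), so a (seed, config, data) triple fully
determines the run.

Protocols: k-fold cross-validation (mean +/- std across folds), repeated
independent tests over consecutive seeds, exhaustive grid search ranked by
mean cross-validation AUC, per-species evaluation of one model, and
species-specific models trained on single-species slices.  Optional
up-/down-sampling of the training set is provided as a dataset transform;
the default imbalance remedy is the focal loss itself.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .curation import DatasetSplit, FoldAssignment, kfold_partition
from .encoders import encode_windows
from .evaluation import MetricsReport, aggregate, evaluate_scores
from .losses import EPS, FocalLossParams
from .model import KcrNet, ModelConfig, build_variant
from .nn.autodiff import Tensor
from .nn.optim import Adam
from .sequence_io import Peptide

__all__ = [
    "TrainConfig",
    "RunResult",
    "encode_dataset",
    "train",
    "cross_validate",
    "independent_runs",
    "grid_search",
    "per_species_eval",
    "species_specific_models",
]

RESAMPLING_MODES = ("none", "upsample_pos", "downsample_neg")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 50
    seed: int = 0
    loss: FocalLossParams = field(default_factory=FocalLossParams)
    resampling: str = "none"
    use_cross_entropy: bool = False  # plain CE instead of focal loss

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.resampling not in RESAMPLING_MODES:
            raise ValueError(
                f"resampling must be one of {RESAMPLING_MODES}, got {self.resampling!r}"
            )


@dataclass
class RunResult:
    model: KcrNet
    history: list[float]  # mean training loss per epoch
    report: MetricsReport | None
    seed: int
    elapsed: float = 0.0


def encode_dataset(
    samples: list[Peptide], scheme: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode peptides for network input: (X, labels, species).

    Matrix schemes give X of shape (n, 29, C); word IDs give (n, 29) ints.
    """
    windows = [s.window for s in samples]
    X = encode_windows(windows, scheme)
    y = np.asarray([s.label for s in samples], dtype=np.int64)
    species = np.asarray([s.species for s in samples])
    return X, y, species


def _resample(y: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Index array implementing the requested class rebalancing (1:1)."""
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if mode == "none" or len(idx_pos) == 0 or len(idx_neg) == 0:
        return np.arange(len(y))
    if mode == "upsample_pos":
        if len(idx_pos) >= len(idx_neg):
            return np.arange(len(y))
        extra = rng.choice(idx_pos, size=len(idx_neg) - len(idx_pos), replace=True)
        return np.r_[np.arange(len(y)), extra]
    # downsample_neg
    if len(idx_neg) <= len(idx_pos):
        return np.arange(len(y))
    keep_neg = rng.choice(idx_neg, size=len(idx_pos), replace=False)
    return np.sort(np.r_[idx_pos, keep_neg])


def _batch_loss(model: KcrNet, xb: np.ndarray, yb: np.ndarray, cfg: TrainConfig) -> Tensor:
    probs = model.forward(xb)
    p1 = probs[:, 1].clip(EPS, 1.0 - EPS)
    yt = Tensor(yb.astype(np.float64))
    pt = yt * p1 + (1.0 - yt) * (1.0 - p1)
    if cfg.use_cross_entropy:
        return (-(pt.log())).mean()
    a, g = cfg.loss.alpha, cfg.loss.gamma
    at = yt * a + (1.0 - yt) * (1.0 - a)
    return ((1.0 - pt).pow(g) * at * (-(pt.log()))).mean()


def train(
    model_config: ModelConfig,
    train_samples: list[Peptide],
    train_config: TrainConfig,
    eval_samples: list[Peptide] | None = None,
) -> RunResult:
    """Train one network; optionally evaluate it on `eval_samples`."""
    t0 = time.time()
    X, y, _ = encode_dataset(train_samples, model_config.input_scheme)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    res_rng = np.random.default_rng([train_config.seed, 0x5E5A])
    keep = _resample(y, train_config.resampling, res_rng)
    X, y = X[keep], y[keep]

    model = build_variant(model_config, seed=train_config.seed)
    model.train()
    opt = Adam(model.parameters(), lr=train_config.learning_rate)
    n = len(y)
    bs = train_config.batch_size
    history: list[float] = []
    for epoch in range(train_config.epochs):
        rng = np.random.default_rng([train_config.seed, epoch])
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, bs):
            sel = perm[i : i + bs]
            opt.zero_grad()
            loss = _batch_loss(model, X[sel], y[sel], train_config)
            val = float(loss.data)
            if math.isnan(val):
                raise RuntimeError(
                    f"NaN loss at epoch {epoch}, batch {i // bs} "
                    f"(lr={train_config.learning_rate}, seed={train_config.seed})"
                )
            loss.backward()
            opt.step()
            losses.append(val * len(sel))
        history.append(sum(losses) / n)
    report = None
    if eval_samples is not None:
        Xe, ye, _ = encode_dataset(eval_samples, model_config.input_scheme)
        report = evaluate_scores(ye, model.predict_proba(Xe))
    return RunResult(
        model=model, history=history, report=report, seed=train_config.seed,
        elapsed=time.time() - t0,
    )


def cross_validate(
    model_config: ModelConfig,
    train_samples: list[Peptide],
    train_config: TrainConfig,
    k: int = 5,
    stratify_by_label: bool = True,
    folds: FoldAssignment | None = None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation; returns per-fold reports and mean +/- std."""
    if folds is None:
        folds = kfold_partition(
            train_samples, k=k, seed=train_config.seed, stratify_by_label=stratify_by_label
        )
    reports: list[MetricsReport] = []
    for j in range(folds.k):
        held = set(folds.fold_indices(j).tolist())
        tr = [s for i, s in enumerate(train_samples) if i not in held]
        va = [s for i, s in enumerate(train_samples) if i in held]
        va_labels = {s.label for s in va}
        if len(va_labels) < 2:
            import warnings

            warnings.warn(f"fold {j} holds a single class; AUC will be undefined", stacklevel=2)
        result = train(model_config, tr, train_config, eval_samples=va)
        reports.append(result.report)
    return reports, aggregate(reports)


def independent_runs(
    model_config: ModelConfig,
    split: DatasetSplit,
    train_config: TrainConfig,
    n_runs: int = 10,
) -> tuple[list[RunResult], MetricsReport]:
    """n_runs trainings with seeds seed+0 .. seed+n-1 on a fixed split."""
    results: list[RunResult] = []
    for r in range(n_runs):
        cfg = replace(train_config, seed=train_config.seed + r)
        results.append(train(model_config, split.train, cfg, eval_samples=split.test))
    agg = aggregate([r.report for r in results])
    return results, agg


_GRID_TARGETS = ("train", "loss", "model")


def _apply_grid_point(
    point: dict, model_config: ModelConfig, train_config: TrainConfig
) -> tuple[ModelConfig, TrainConfig]:
    mc, tc = model_config, train_config
    for key, value in point.items():
        if hasattr(tc, key) and key != "loss":
            tc = replace(tc, **{key: value})
        elif hasattr(tc.loss, key):
            tc = replace(tc, loss=replace(tc.loss, **{key: value}))
        elif hasattr(mc, key):
            d = mc.to_dict()
            d[key] = value
            mc = ModelConfig.from_dict(d)
        else:
            raise ValueError(f"unknown hyperparameter {key!r}")
    return mc, tc


def grid_search(
    grid: dict[str, list],
    model_config: ModelConfig,
    train_samples: list[Peptide],
    train_config: TrainConfig,
    k: int = 5,
) -> tuple[dict, list[dict]]:
    """Exhaustive grid search ranked by mean cross-validation AUC.

    Returns (best point, full results table).  Ties on AUC keep the first
    point in iteration order.
    """
    if not grid:
        raise ValueError("empty grid")
    import itertools

    keys = list(grid)
    table: list[dict] = []
    best: dict | None = None
    best_auc = -np.inf
    for values in itertools.product(*(grid[k_] for k_ in keys)):
        point = dict(zip(keys, values))
        mc, tc = _apply_grid_point(point, model_config, train_config)
        _, agg = cross_validate(mc, train_samples, tc, k=k)
        row = {**point, "mean_AUC": agg.AUC, "report": agg}
        table.append(row)
        auc = -np.inf if agg.AUC is None else agg.AUC
        if auc > best_auc:
            best_auc = auc
            best = point
    return best, table


def per_species_eval(
    model: KcrNet, test_samples: list[Peptide]
) -> dict[str, MetricsReport]:
    """Metric suite per species plus an 'overall' entry."""
    X, y, species = encode_dataset(test_samples, model.config.input_scheme)
    scores = model.predict_proba(X)
    out: dict[str, MetricsReport] = {"overall": evaluate_scores(y, scores)}
    for sp in sorted(set(species.tolist())):
        sel = species == sp
        out[sp] = evaluate_scores(y[sel], scores[sel])
    return out


def species_specific_models(
    split: DatasetSplit,
    species_list: list[str],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> dict[str, RunResult]:
    """One model per species, trained and evaluated on that species only."""
    out: dict[str, RunResult] = {}
    for sp in species_list:
        tr = [s for s in split.train if s.species == sp]
        te = [s for s in split.test if s.species == sp]
        if not tr or not te:
            raise ValueError(f"species {sp!r} missing from train or test set")
        out[sp] = train(model_config, tr, train_config, eval_samples=te)
    return out
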