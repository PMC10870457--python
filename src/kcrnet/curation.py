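"""Redundancy reduction and dataset partitioning.

Deduplication is a greedy identity clustering of the fixed-length 29-mer
windows: samples are visited in a deterministic order (positives first, then
lexicographic), each is kept unless it matches a previously retained window
at more than the identity threshold.  Identity between two windows is the
number of agreeing positions divided by 29, with X matching nothing (X
encodes absence of sequence, not a residue) — so two X's at the same
position do not count as a match.

The train/test split is stratified by (species, label): within each stratum
a seeded shuffle sends floor(ratio * n) samples to the training side, which
reproduces the published per-species counts (e.g. 3550 wheat positives at
ratio 0.7 -> 2484 train / 1066 test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import WINDOW_LENGTH, X_INDEX, encode_indices
from .sequence_io import Peptide

__all__ = [
    "DatasetSplit",
    "FoldAssignment",
    "pair_identity",
    "deduplicate",
    "species_stratified_split",
    "kfold_partition",
]


@dataclass
class DatasetSplit:
    train: list[Peptide]
    test: list[Peptide]
    seed: int
    ratio: float


@dataclass
class FoldAssignment:
    """fold[i] is the fold index (in [0, k)) of sample i."""

    fold: np.ndarray
    k: int

    def fold_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold == j)


def pair_identity(a: str, b: str) -> float:
    """Fraction of the 29 positions where the two windows agree (X never matches)."""
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "X")
    return matches / WINDOW_LENGTH


def _dedup_order(samples: list[Peptide]) -> list[int]:
    return sorted(range(len(samples)), key=lambda i: (-samples[i].label, samples[i].window))


def deduplicate(samples: list[Peptide], identity_threshold: float = 0.40) -> list[Peptide]:
    """Greedy identity clustering; returns retained samples in input order.

    Positives are visited first so that, between a redundant positive and
    negative, the positive is retained (this also removes potential false
    negatives: an unannotated window nearly identical to a known site).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    if not samples:
        return []
    codes = np.stack([encode_indices(s.window) for s in samples])
    order = _dedup_order(samples)
    max_matches = identity_threshold * WINDOW_LENGTH  # retained iff matches <= this
    reps = np.empty((0, WINDOW_LENGTH), dtype=codes.dtype)
    kept: list[int] = []
    for i in order:
        c = codes[i]
        if reps.shape[0]:
            m = ((reps == c) & (c != X_INDEX)).sum(axis=1)
            if (m > max_matches).any():
                continue
        reps = np.vstack([reps, c])
        kept.append(i)
    kept.sort()
    return [samples[i] for i in kept]


def species_stratified_split(
    samples: list[Peptide], ratio: float = 0.7, seed: int = 0
) -> DatasetSplit:
    """Seeded 7:3-style split stratified by (species, label).

    Within each stratum, floor(ratio * n) samples are shuffled into the
    training side.  Empty strata are skipped.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(samples):
        strata.setdefault((s.species, s.label), []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(ratio * len(idx)))
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return DatasetSplit(
        train=[samples[i] for i in train_idx],
        test=[samples[i] for i in test_idx],
        seed=seed,
        ratio=ratio,
    )


def kfold_partition(
    samples: list[Peptide] | int,
    k: int = 5,
    seed: int = 0,
    stratify_by_label: bool = True,
) -> FoldAssignment:
    """Seeded shuffle + round-robin fold assignment.

    With `stratify_by_label` (the default) the shuffle and round-robin run
    within each label class, so every fold receives an equal share of
    positives and negatives (within 1).  Accepts either the sample list or
    a bare count (count implies no stratification).
    """
    if isinstance(samples, int):
        n = samples
        labels = None
    else:
        n = len(samples)
        labels = np.asarray([s.label for s in samples])
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    if stratify_by_label and labels is not None:
        counter = 0
        for lab in (1, 0):
            idx = np.flatnonzero(labels == lab)
            perm = rng.permutation(len(idx))
            for j, i in enumerate(idx[perm]):
                fold[i] = (counter + j) % k
            counter += len(idx)
    else:
        perm = rng.permutation(n)
        fold[perm] = np.arange(n) % k
    return FoldAssignment(fold=fold, k=k)
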