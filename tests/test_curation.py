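"""Deduplication, stratified splitting, and k-fold partitioning."""

import numpy as np
import pytest

from conftest import make_peptide, make_window
from kcrnet.curation import (
    deduplicate,
    kfold_partition,
    pair_identity,
    species_stratified_split,
)


def _window_agreeing_at(base: str, n_agree: int) -> str:
    """A window sharing exactly `n_agree` non-X positions with `base`.

    The center K always agrees; remaining agreement positions keep the base
    residue, all others are swapped to a different residue.
    """
    assert 1 <= n_agree <= 29
    out = []
    budget = n_agree - 1  # the center K agreement is mandatory
    for i, ch in enumerate(base):
        if i == 14:
            out.append("K")
        elif budget > 0:
            out.append(ch)
            budget -= 1
        else:
            out.append("A" if ch != "A" else "G")
    return "".join(out)


class TestDeduplicate:
    def test_identical_windows_collapse(self):
        w = make_window(np.random.default_rng(0))
        kept = deduplicate([make_peptide(w), make_peptide(w)])
        assert len(kept) == 1

    def test_fully_distinct_windows_survive(self, rng):
        base = make_window(rng)
        other = _window_agreeing_at(base, 1)  # only the center K agrees
        assert pair_identity(base, other) == pytest.approx(1 / 29)
        assert len(deduplicate([make_peptide(base), make_peptide(other)])) == 2

    def test_threshold_boundary_12_vs_11_of_29(self, rng):
        """12/29 ~= 0.414 > 0.40 drops the pair; 11/29 ~= 0.379 keeps both."""
        base = make_window(rng)
        w12 = _window_agreeing_at(base, 12)
        w11 = _window_agreeing_at(base, 11)
        # brute-force identity oracle
        assert sum(a == b and a != "X" for a, b in zip(base, w12)) == 12
        assert sum(a == b and a != "X" for a, b in zip(base, w11)) == 11
        assert len(deduplicate([make_peptide(base), make_peptide(w12)])) == 1
        assert len(deduplicate([make_peptide(base), make_peptide(w11)])) == 2

    def test_x_matches_nothing(self):
        a = make_peptide("X" * 14 + "K" + "X" * 14)
        b = make_peptide("X" * 14 + "K" + "X" * 14)
        # identical strings, but only the K position can match
        assert pair_identity(a.window, b.window) == pytest.approx(1 / 29)
        assert len(deduplicate([a, b])) == 2

    def test_positive_preferred_over_negative(self, rng):
        w = make_window(rng)
        neg = make_peptide(w, label=0, pid="neg")
        pos = make_peptide(w, label=1, pid="pos")
        kept = deduplicate([neg, pos])
        assert [k.label for k in kept] == [1]

    def test_no_retained_pair_above_threshold(self, rng):
        """Exhaustive pairwise check on 300 windows with planted redundancy."""
        windows = [make_window(rng) for _ in range(150)]
        for i in range(100):  # near-duplicates of the first 100
            windows.append(_window_agreeing_at(windows[i], int(rng.integers(10, 29))))
        samples = [make_peptide(w, pid=f"P{i}") for i, w in enumerate(windows)]
        kept = deduplicate(samples, identity_threshold=0.40)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pair_identity(kept[i].window, kept[j].window) <= 0.40

    def test_bad_threshold(self, small_samples):
        with pytest.raises(ValueError, match="identity_threshold"):
            deduplicate(small_samples, identity_threshold=1.5)


class TestSpeciesStratifiedSplit:
    @staticmethod
    def _mk(n_pos, n_neg, species, rng):
        out = [make_peptide(make_window(rng), 1, species, f"{species}p{i}") for i in range(n_pos)]
        out += [make_peptide(make_window(rng), 0, species, f"{species}n{i}") for i in range(n_neg)]
        return out

    def test_exact_arithmetic_ten_ten(self, rng):
        samples = self._mk(10, 10, "wheat", rng)
        split = species_stratified_split(samples, ratio=0.7, seed=0)
        assert sum(s.label for s in split.train) == 7
        assert sum(1 - s.label for s in split.train) == 7
        assert len(split.test) == 6

    def test_wheat_sized_stratum_floor_arithmetic(self, rng):
        """A 3550-sample stratum at ratio 0.7 -> floor(2485.0) = 2485 train.

        0.7 * 3550 is exactly 2485, so the uniform floor rule sends 2485
        samples to the training side and 1065 to the test side.
        """
        samples = self._mk(3550, 0, "wheat", rng)
        # single-class stratum is allowed here; we only check the positive side
        split = species_stratified_split(samples, ratio=0.7, seed=3)
        assert len(split.train) == 2485
        assert len(split.test) == 1065

    @pytest.mark.parametrize("n,expected_train", [(1172, 820), (946, 662), (3503, 2452)])
    def test_fractional_stratum_sizes_floor(self, rng, n, expected_train):
        """Strata with fractional 0.7*n land on the floor for the train side."""
        samples = self._mk(n, 0, "rice", rng)
        split = species_stratified_split(samples, ratio=0.7, seed=0)
        assert len(split.train) == expected_train
        assert len(split.test) == n - expected_train

    def test_seed_changes_membership_not_sizes(self, rng):
        samples = self._mk(10, 10, "rice", rng)
        s1 = species_stratified_split(samples, seed=1)
        s2 = species_stratified_split(samples, seed=2)
        assert len(s1.train) == len(s2.train)
        assert {p.protein_id for p in s1.train} != {p.protein_id for p in s2.train}

    def test_partition_is_exact_and_disjoint(self, small_samples):
        split = species_stratified_split(small_samples, seed=7)
        key = lambda p: (p.window, p.protein_id, p.position)
        train_keys = {key(p) for p in split.train}
        test_keys = {key(p) for p in split.test}
        assert not train_keys & test_keys
        assert len(split.train) + len(split.test) == len(small_samples)

    def test_bad_ratio(self, small_samples):
        with pytest.raises(ValueError, match="ratio"):
            species_stratified_split(small_samples, ratio=1.2)


class TestKfoldPartition:
    def test_even_sizes(self):
        fa = kfold_partition(10, k=5)
        assert sorted(np.bincount(fa.fold).tolist()) == [2, 2, 2, 2, 2]

    def test_uneven_sizes(self):
        fa = kfold_partition(11, k=5)
        assert sorted(np.bincount(fa.fold).tolist(), reverse=True) == [3, 2, 2, 2, 2]

    def test_stratified_class_balance(self, rng):
        samples = [
            make_peptide(make_window(rng), label=int(i < 20), pid=f"P{i}") for i in range(100)
        ]
        fa = kfold_partition(samples, k=5, seed=0, stratify_by_label=True)
        labels = np.array([s.label for s in samples])
        for j in range(5):
            idx = fa.fold_indices(j)
            assert labels[idx].sum() == 4
            assert len(idx) == 20

    def test_partition_and_reproducibility(self, small_samples):
        fa1 = kfold_partition(small_samples, k=4, seed=9)
        fa2 = kfold_partition(small_samples, k=4, seed=9)
        assert np.array_equal(fa1.fold, fa2.fold)
        assert sorted(np.concatenate([fa1.fold_indices(j) for j in range(4)]).tolist()) == list(
            range(len(small_samples))
        )

    def test_k_larger_than_n(self):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_partition(3, k=5)
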