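"""Position-specific residue enrichment around crotonylation sites.

A simplified sequence-logo statistic in the spirit of pLogo: for each
window offset (-14 .. +14, excluding the fixed central K) and each of the
21 residue symbols, compare the foreground (positive windows) count against
the background (negative windows) count with

    log-odds = ln((f + c) / (F + 21c)) - ln((b + c) / (B + 21c)),   c = 0.5

(pseudo-count c keeps zero counts finite) and a two-sided binomial test of
the foreground count given the background frequency.  Positive log-odds
means over-representation.  This is a rank/significance statistic, not a
re-implementation of pLogo's residue-height rendering; p-values are raw,
with the number of tests (28 positions x 21 residues) stated in the output
for any multiplicity correction the caller wants to apply.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .alphabet import ALPHABET, CENTER, WINDOW_LENGTH, encode_indices
from .sequence_io import Peptide

__all__ = ["position_frequencies", "enrichment", "N_TESTS"]

N_TESTS = (WINDOW_LENGTH - 1) * len(ALPHABET)  # 28 x 21 tested cells


def position_frequencies(samples: list[Peptide], label: int) -> np.ndarray:
    """Count matrix (29, 21): residue occurrences per window position.

    Only samples with the given label contribute; every column sums to the
    number of such samples (X included).
    """
    windows = [s.window for s in samples if s.label == label]
    if not windows:
        raise ValueError(f"no samples with label {label}")
    codes = np.stack([encode_indices(w) for w in windows])
    counts = np.zeros((WINDOW_LENGTH, len(ALPHABET)), dtype=np.int64)
    for pos in range(WINDOW_LENGTH):
        counts[pos] = np.bincount(codes[:, pos], minlength=len(ALPHABET))
    return counts


def enrichment(
    fore_counts: np.ndarray, back_counts: np.ndarray, pseudo_count: float = 0.5
) -> pd.DataFrame:
    """Per-(offset, residue) log-odds and binomial p-values.

    `fore_counts` and `back_counts` are (29, 21) matrices as produced by
    :func:`position_frequencies`.  The central position (offset 0, fixed K)
    is excluded.  Returns a DataFrame sorted by p-value with columns
    offset, residue, fore_count, back_count, log_odds, p_value, direction,
    n_tests.
    """
    fore_counts = np.asarray(fore_counts)
    back_counts = np.asarray(back_counts)
    if fore_counts.shape != back_counts.shape or fore_counts.shape != (
        WINDOW_LENGTH,
        len(ALPHABET),
    ):
        raise ValueError("count matrices must both be (29, 21)")
    c = pseudo_count
    rows = []
    for pos in range(WINDOW_LENGTH):
        if pos == CENTER:
            continue
        offset = pos - CENTER
        F = int(fore_counts[pos].sum())
        B = int(back_counts[pos].sum())
        if F == 0 or B == 0:
            raise ValueError("empty foreground or background at a position")
        for j, residue in enumerate(ALPHABET):
            f = int(fore_counts[pos, j])
            b = int(back_counts[pos, j])
            log_odds = math.log((f + c) / (F + c * 21)) - math.log((b + c) / (B + c * 21))
            p_bg = (b + c) / (B + c * 21)
            p_value = binomtest(f, F, p_bg, alternative="two-sided").pvalue
            rows.append(
                dict(
                    offset=offset,
                    residue=residue,
                    fore_count=f,
                    back_count=b,
                    log_odds=log_odds,
                    p_value=p_value,
                    direction="over" if log_odds > 0 else "under",
                    n_tests=N_TESTS,
                )
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["p_value", "offset"], kind="mergesort").reset_index(drop=True)


def enrichment_from_samples(samples: list[Peptide], pseudo_count: float = 0.5) -> pd.DataFrame:
    """Convenience wrapper: positives are foreground, negatives background."""
    fore = position_frequencies(samples, 1)
    back = position_frequencies(samples, 0)
    return enrichment(fore, back, pseudo_count=pseudo_count)
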