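"""Shared fixtures: small deterministic datasets and window builders."""

import numpy as np
import pytest
from hypothesis import settings

from kcrnet.alphabet import ALPHABET, CENTER, STANDARD_AA, WINDOW_LENGTH
from kcrnet.sequence_io import Peptide

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def make_window(rng: np.random.Generator, alphabet: str = STANDARD_AA) -> str:
    """A random 29-mer over `alphabet` with the mandatory central K."""
    chars = [alphabet[i] for i in rng.integers(0, len(alphabet), WINDOW_LENGTH)]
    chars[CENTER] = "K"
    return "".join(chars)


def make_peptide(window: str, label: int = 0, species: str = "wheat", pid: str = "P1") -> Peptide:
    return Peptide(window=window, label=label, species=species, protein_id=pid, position=15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_windows(rng):
    """1,000 random windows over the full 21-letter alphabet."""
    return [make_window(rng, ALPHABET) for _ in range(1000)]


@pytest.fixture
def small_samples(rng):
    """60 random peptides across two species, ~1:3 imbalance."""
    out = []
    for i in range(60):
        out.append(
            make_peptide(
                make_window(rng),
                label=int(rng.random() < 0.25),
                species=("wheat", "rice")[i % 2],
                pid=f"P{i:03d}",
            )
        )
    return out
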