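"""Six numeric representations of a 29-mer peptide window.

========  =========  ==========================================================
scheme    shape      description
========  =========  ==========================================================
aac       (1, 21)    residue frequencies over the 21-letter alphabet
egaac     (1, 5)     proportions of five physicochemical groups (X in none)
be        (29, 21)   one-hot (binary) encoding per position
we        (29,)      integer word IDs in [0, 20]; the trainable 10-dim
                     embedding lives inside the network
aaindex   (29, 29)   29 physicochemical index values per residue
blosum62  (29, 21)   BLOSUM62 substitution-score row per residue
========  =========  ==========================================================

Every encoder is a pure function of the window string.  The physicochemical
table ships as an editable TSV of 29 published residue scales; the exact
index selection is configuration, not a fixed constant of the method, and
each index is min-max scaled to [0, 1] over the 20 real residues with the
X row forced to zero (X encodes absent sequence).  BLOSUM62 scores are used
raw, as integers.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import ALPHABET, STANDARD_AA, WINDOW_LENGTH, encode_indices, validate_window

__all__ = [
    "AAIndexTable",
    "encode_aac",
    "encode_egaac",
    "encode_binary",
    "decode_binary",
    "encode_word_ids",
    "decode_word_ids",
    "encode_aaindex",
    "encode_blosum62",
    "get_encoder",
    "ENCODER_NAMES",
    "EGAAC_GROUPS",
]

EGAAC_GROUPS: tuple[tuple[str, str], ...] = (
    ("aliphatic", "GAVLMI"),
    ("aromatic", "FYW"),
    ("positive", "KRH"),
    ("negative", "DE"),
    ("uncharged", "STCPNQ"),
)


class AAIndexTable:
    """29 named physicochemical indices, each a 21-vector over the alphabet.

    Loaded from TSV (``index_id`` then one column per alphabet letter);
    values are min-max scaled to [0, 1] per index over the 20 real residues
    and the X column is zeroed.
    """

    N_INDICES = 29

    def __init__(self, names: list[str], values: np.ndarray):
        if len(names) != self.N_INDICES or values.shape != (self.N_INDICES, 21):
            raise ValueError(
                f"expected {self.N_INDICES} indices x 21 residues, "
                f"got {len(names)} x {values.shape}"
            )
        self.names = list(names)
        self.values = values.astype(np.float64)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexTable":
        names: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "index_id" or header[1:] != list(ALPHABET):
                raise ValueError(
                    f"{path}: header must be 'index_id' followed by the 21 alphabet letters"
                )
            for line_number, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 22:
                    raise ValueError(
                        f"{path} line {line_number}: expected 22 columns, got {len(parts)}"
                    )
                names.append(parts[0])
                try:
                    rows.append([float(v) for v in parts[1:]])
                except ValueError as e:
                    raise ValueError(f"{path} line {line_number}: {e}") from e
        raw = np.asarray(rows)
        # min-max scale each index over the 20 real residues; X row -> 0
        lo = raw[:, :20].min(axis=1, keepdims=True)
        hi = raw[:, :20].max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        scaled = np.empty_like(raw)
        scaled[:, :20] = (raw[:, :20] - lo) / span
        scaled[:, 20] = 0.0
        return cls(names, scaled)

    @classmethod
    def default(cls) -> "AAIndexTable":
        return cls.from_tsv(files("kcrnet") / "data" / "aaindex_default.tsv")


_DEFAULT_TABLE: AAIndexTable | None = None


def _default_table() -> AAIndexTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AAIndexTable.default()
    return _DEFAULT_TABLE


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 rows for the 21-letter alphabet (X uses its standard row)."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.empty((21, 21), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a][b]
    return out


_BLOSUM62: np.ndarray | None = None


def _blosum62() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _blosum62_matrix()
    return _BLOSUM62


def encode_aac(window: str) -> np.ndarray:
    """Residue frequencies: (1, 21) vector summing to 1."""
    validate_window(window)
    counts = np.bincount(encode_indices(window), minlength=21).astype(np.float64)
    return (counts / WINDOW_LENGTH)[None, :]


def encode_egaac(window: str) -> np.ndarray:
    """Grouped composition: (1, 5) proportions; X counts toward no group."""
    validate_window(window)
    out = np.zeros((1, 5))
    for g, (_, members) in enumerate(EGAAC_GROUPS):
        out[0, g] = sum(window.count(ch) for ch in members)
    return out / WINDOW_LENGTH

def encode_binary(window: str) -> np.ndarray:
    """One-hot matrix (29, 21): row i marks the residue at position i."""
    validate_window(window)
    out = np.zeros((WINDOW_LENGTH, 21))
    out[np.arange(WINDOW_LENGTH), encode_indices(window)] = 1.0
    return out


def decode_binary(matrix: np.ndarray) -> str:
    return "".join(ALPHABET[j] for j in np.asarray(matrix).argmax(axis=1))


def encode_word_ids(window: str) -> np.ndarray:
    """Integer IDs (29,) in [0, 20]: each residue's index in the alphabet."""
    validate_window(window)
    return encode_indices(window)


def decode_word_ids(ids: np.ndarray) -> str:
    return "".join(ALPHABET[int(j)] for j in np.asarray(ids))


def encode_aaindex(window: str, table: AAIndexTable | None = None) -> np.ndarray:
    """(29, 29): the 29 scaled index values of the residue at each position."""
    validate_window(window)
    table = table or _default_table()
    return table.values.T[encode_indices(window)]


def encode_blosum62(window: str) -> np.ndarray:
    """(29, 21): the BLOSUM62 row of the residue at each position (raw scores)."""
    validate_window(window)
    return _blosum62()[encode_indices(window)]


ENCODER_NAMES = ("aac", "egaac", "be", "we", "aaindex", "blosum62")

_REGISTRY = {
    "aac": encode_aac,
    "egaac": encode_egaac,
    "be": encode_binary,
    "we": encode_word_ids,
    "aaindex": encode_aaindex,
    "blosum62": encode_blosum62,
}


def get_encoder(name: str):
    """Look up an encoder by its registry name (see ENCODER_NAMES)."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise KeyError(f"unknown encoding {name!r}; choose from {ENCODER_NAMES}") from None


def encode_windows(windows: list[str], scheme: str, table: AAIndexTable | None = None) -> np.ndarray:
    """Vectorized encoding of many windows: stacked along a leading axis."""
    enc = get_encoder(scheme)
    if scheme == "aaindex" and table is not None:
        return np.stack([enc(w, table) for w in windows])
    return np.stack([enc(w) for w in windows])
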