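"""The 21-letter residue alphabet shared by every component.

The 20 standard amino acids in fixed alphabetical one-letter order, then
``X``.  ``X`` stands for absent sequence (window padding past a protein
terminus) and for any non-standard residue letter; it is treated as a 21st
symbol by the encoders but belongs to no physicochemical group and matches
nothing in identity calculations.  The order is serialized with every model
artifact and must never change once published.
"""

from __future__ import annotations

ALPHABET: str = "ACDEFGHIKLMNPQRSTVWYX"
STANDARD_AA: str = ALPHABET[:20]
X_INDEX: int = 20
INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: letters normalized to X when sequences are read (ambiguity codes,
#: rare residues, stop marker)
NON_STANDARD: frozenset[str] = frozenset("BJOUZ*")

WINDOW_LENGTH: int = 29
FLANK: int = 14
CENTER: int = FLANK  # 0-based index of the central K in a window


def normalize_sequence(seq: str) -> str:
    """Uppercase and map non-standard letters to X; reject anything else."""
    out = []
    for i, ch in enumerate(seq.upper()):
        if ch in INDEX:
            out.append(ch)
        elif ch in NON_STANDARD:
            out.append("X")
        else:
            raise ValueError(f"invalid residue letter {ch!r} at position {i + 1}")
    return "".join(out)


def validate_window(window: str) -> None:
    """Raise if `window` is not a 29-mer over the alphabet with central K."""
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window length {len(window)} != {WINDOW_LENGTH}")
    bad = set(window) - set(ALPHABET)
    if bad:
        raise ValueError(f"window contains letters outside the alphabet: {sorted(bad)}")
    if window[CENTER] != "K":
        raise ValueError(f"window center is {window[CENTER]!r}, expected 'K'")


def encode_indices(window: str):
    """Window string -> integer codes over the alphabet (length 29)."""
    import numpy as np

    return np.fromiter((INDEX[c] for c in window), dtype=np.int64, count=len(window))
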