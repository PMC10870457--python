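"""Protein sequences, site annotations, and peptide-window extraction.

Proteins arrive as FASTA, crotonylation sites as a tab- or comma-separated
table (``protein_id``, ``position``, ``species``; positions 1-based).  Every
lysine in an annotated protein yields one 29-residue window centered on the
K, padded with X where the window runs past a terminus; the window is the
positive class exactly when its (protein, position) pair is annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .alphabet import FLANK, WINDOW_LENGTH, normalize_sequence

__all__ = [
    "ProteinRecord",
    "SiteAnnotation",
    "Peptide",
    "read_fasta",
    "read_site_annotations",
    "extract_window",
    "build_samples",
    "write_samples",
    "read_samples",
]

SAMPLE_COLUMNS = ["window", "label", "species", "protein_id", "position"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 21-letter alphabet (unknowns already X)."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")


@dataclass(frozen=True)
class SiteAnnotation:
    """A 1-based crotonylated-lysine position on a named protein."""

    protein_id: str
    position: int
    species: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(
                f"annotation {self.protein_id}: position must be >= 1, got {self.position}"
            )


@dataclass(frozen=True)
class Peptide:
    """A 29-mer window centered on K with its label and provenance."""

    window: str
    label: int
    species: str
    protein_id: str
    position: int  # 1-based center position in the source protein

    def __post_init__(self):
        from .alphabet import validate_window

        validate_window(self.window)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read FASTA into ProteinRecords, normalizing non-standard letters to X.

    Duplicate IDs are an error; an empty file returns an empty list with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path} line {line_number}: expected FASTA header starting with '>'"
                    )
                break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA ID: {entry.id!r}")
        seen.add(entry.id)
        try:
            seq = normalize_sequence(str(entry.seq))
        except ValueError as e:
            raise ValueError(f"protein {entry.id}: {e}") from e
        records.append(ProteinRecord(id=entry.id, sequence=seq, species=species))
    if not records:
        warnings.warn(f"no FASTA entries found in {path}", stacklevel=2)
    return records


def read_site_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site table with header columns protein_id, position, species.

    The separator (tab or comma) is sniffed from the header line.  Rows with
    non-integer or non-positive positions are rejected with their row number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"protein_id", "position", "species"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    out: list[SiteAnnotation] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row.position)
        try:
            pos = int(raw)
        except ValueError:
            raise ValueError(f"{path} row {row_number}: non-integer position {raw!r}")
        if pos < 1:
            raise ValueError(f"{path} row {row_number}: position must be >= 1, got {pos}")
        out.append(
            SiteAnnotation(protein_id=str(row.protein_id), position=pos, species=str(row.species))
        )
    return out


def extract_window(protein: ProteinRecord, position: int, flank: int = FLANK) -> str:
    """Window of 2*flank+1 residues centered on the K at `position` (1-based).

    Positions outside the protein are filled with X so the window length is
    always 2*flank+1.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"protein {protein.id}: position {position} outside sequence of length {len(seq)}"
        )
    if seq[position - 1] != "K":
        raise ValueError(
            f"protein {protein.id}: residue at position {position} is "
            f"{seq[position - 1]!r}, expected 'K'"
        )
    i = position - 1
    left = seq[max(0, i - flank) : i]
    right = seq[i + 1 : i + 1 + flank]
    return "X" * (flank - len(left)) + left + "K" + right + "X" * (flank - len(right))


def build_samples(
    proteins: list[ProteinRecord], annotations: list[SiteAnnotation]
) -> list[Peptide]:
    """One Peptide per K residue of every annotated protein.

    A window is labeled 1 exactly when its (protein_id, position) appears in
    `annotations`; every other K in the same proteins becomes a negative.
    Negatives are drawn only from annotated proteins, so unannotated records
    in `proteins` contribute nothing.
    """
    by_id = {p.id: p for p in proteins}
    unresolved = sorted({a.protein_id for a in annotations} - set(by_id))
    if unresolved:
        raise ValueError(f"annotations reference unknown protein(s): {unresolved}")
    positive: dict[str, set[int]] = {}
    for a in annotations:
        prot = by_id[a.protein_id]
        if prot.sequence[a.position - 1 : a.position] != "K":
            raise ValueError(
                f"annotation at {a.protein_id}:{a.position} does not point at a K residue"
            )
        positive.setdefault(a.protein_id, set()).add(a.position)
    samples: list[Peptide] = []
    for pid in positive:
        prot = by_id[pid]
        species = prot.species
        for i, ch in enumerate(prot.sequence):
            if ch != "K":
                continue
            pos = i + 1
            samples.append(
                Peptide(
                    window=extract_window(prot, pos),
                    label=int(pos in positive[pid]),
                    species=species,
                    protein_id=pid,
                    position=pos,
                )
            )
    return samples


def write_samples(samples: list[Peptide], path: str | Path) -> None:
    """Serialize peptides as TSV with columns window, label, species, protein_id, position."""
    df = pd.DataFrame(
        [(s.window, s.label, s.species, s.protein_id, s.position) for s in samples],
        columns=SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[Peptide]:
    df = pd.read_csv(path, sep="\t", dtype={"window": str, "species": str, "protein_id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing sample column(s) {sorted(missing)}")
    return [
        Peptide(
            window=r.window,
            label=int(r.label),
            species=str(r.species),
            protein_id=str(r.protein_id),
            position=int(r.position),
        )
        for r in df.itertuples(index=False)
    ]
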