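"""FASTA/annotation reading, window extraction, and sample construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kcrnet.alphabet import CENTER, STANDARD_AA, WINDOW_LENGTH, normalize_sequence
from kcrnet.sequence_io import (
    Peptide,
    ProteinRecord,
    SiteAnnotation,
    build_samples,
    extract_window,
    read_fasta,
    read_samples,
    read_site_annotations,
    write_samples,
)


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nMKKA\n")
        records = read_fasta(p)
        assert len(records) == 1
        assert records[0].id == "p1"
        assert records[0].sequence == "MKKA"

    def test_nonstandard_letters_become_x(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nMUKB\n")  # U (selenocysteine), B (ambiguous)
        assert read_fasta(p)[0].sequence == "MXKX"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nMK\n>p1\nKK\n")
        with pytest.raises(ValueError, match="p1"):
            read_fasta(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(p) == []

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("MKKA\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(p)

    def test_invalid_letter_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nMK7A\n")
        with pytest.raises(ValueError, match="p1"):
            read_fasta(p)


class TestReadSiteAnnotations:
    def test_tab_and_comma_dialects(self, tmp_path):
        for sep in ("\t", ","):
            p = tmp_path / "sites.txt"
            p.write_text(f"protein_id{sep}position{sep}species\np1{sep}2{sep}wheat\n")
            (ann,) = read_site_annotations(p)
            assert ann == SiteAnnotation("p1", 2, "wheat")

    def test_nonpositive_position_names_row(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("protein_id\tposition\tspecies\np1\t0\twheat\n")
        with pytest.raises(ValueError, match="row 2"):
            read_site_annotations(p)

    def test_non_integer_position(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("protein_id\tposition\tspecies\np1\tx\twheat\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_site_annotations(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("protein_id\tposition\np1\t2\n")
        with pytest.raises(ValueError, match="species"):
            read_site_annotations(p)

    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "sites.tsv"
        p.write_text("protein_id\tposition\tspecies\n")
        assert read_site_annotations(p) == []


class TestExtractWindow:
    def test_heavy_left_padding(self):
        prot = ProteinRecord("p", "MK")
        assert extract_window(prot, 2) == "X" * 13 + "MK" + "X" * 14

    def test_exact_fit_no_padding(self):
        seq = "A" * 14 + "K" + "A" * 14
        assert extract_window(ProteinRecord("p", seq), 15) == seq

    def test_center_not_lysine(self):
        with pytest.raises(ValueError, match="expected 'K'"):
            extract_window(ProteinRecord("p", "AKA"), 1)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            extract_window(ProteinRecord("p", "AK"), 5)

    @given(
        seq=st.text(alphabet=STANDARD_AA, min_size=1, max_size=80),
        pos0=st.integers(min_value=0, max_value=79),
    )
    def test_window_invariants(self, seq, pos0):
        """Any K in any protein yields a 29-mer with K at the center."""
        if pos0 >= len(seq):
            pos0 = pos0 % len(seq)
        seq = seq[:pos0] + "K" + seq[pos0 + 1 :]
        w = extract_window(ProteinRecord("p", seq), pos0 + 1)
        assert len(w) == WINDOW_LENGTH
        assert w[CENTER] == "K"
        # padding-free center reversibility
        assert w[CENTER] == seq[pos0]
        # non-X part matches the source sequence
        lo = max(0, pos0 - 14)
        assert w.strip("X").find(seq[lo : pos0 + 1][-3:]) != -1 or len(seq) < 3


class TestBuildSamples:
    def test_labels_follow_annotations(self):
        prot = ProteinRecord("p1", "AKAKA", species="rice")
        peps = build_samples([prot], [SiteAnnotation("p1", 2, "rice")])
        assert len(peps) == 2
        by_pos = {p.position: p for p in peps}
        assert by_pos[2].label == 1 and by_pos[4].label == 0
        assert all(p.species == "rice" for p in peps)

    def test_protein_without_k_contributes_nothing(self):
        prots = [ProteinRecord("p1", "AKA"), ProteinRecord("p2", "AAA")]
        peps = build_samples(prots, [SiteAnnotation("p1", 2, "")])
        assert {p.protein_id for p in peps} == {"p1"}

    def test_counts_match_brute_force_enumeration(self, rng):
        """5 proteins, 3 annotated K's out of 12 total -> 12 peptides, 3 positive."""
        proteins, annotations, total_k = [], [], 0
        k_positions = []
        while total_k < 12:
            proteins, k_positions, total_k = [], [], 0
            for i in range(5):
                seq = "".join(STANDARD_AA[j] for j in rng.integers(0, 20, 40))
                proteins.append(ProteinRecord(f"p{i}", seq))
                for pos0, ch in enumerate(seq):
                    if ch == "K":
                        k_positions.append((f"p{i}", pos0 + 1))
                total_k = len(k_positions)
            k_positions = k_positions[:12]
            total_k = len(k_positions)
        proteins = [
            ProteinRecord(p.id, _truncate_after_12k(p.sequence, k_positions, p.id))
            for p in proteins
        ]
        annotated = [k_positions[j] for j in (0, 5, 11)]
        annotations = [SiteAnnotation(pid, pos, "") for pid, pos in annotated]
        peps = build_samples(proteins, annotations)
        # brute-force oracle: scan every protein for K
        expected = sum(p.sequence.count("K") for p in proteins if p.id in {a.protein_id for a in annotations})
        assert len(peps) == expected
        assert sum(p.label for p in peps) == 3

    def test_unknown_protein_listed(self):
        with pytest.raises(ValueError, match="ghost"):
            build_samples([ProteinRecord("p1", "AK")], [SiteAnnotation("ghost", 1, "")])

    def test_annotation_at_non_k(self):
        with pytest.raises(ValueError, match="does not point at a K"):
            build_samples([ProteinRecord("p1", "AK")], [SiteAnnotation("p1", 1, "")])

    def test_peptide_count_equals_k_count(self, rng):
        seq = "".join(STANDARD_AA[j] for j in rng.integers(0, 20, 200))
        if "K" not in seq:
            seq += "K"
        prot = ProteinRecord("p", seq)
        first_k = seq.index("K") + 1
        peps = build_samples([prot], [SiteAnnotation("p", first_k, "")])
        assert len(peps) == seq.count("K")


def _truncate_after_12k(seq: str, kept: list, pid: str) -> str:
    """Remove K's beyond the 12 kept (turn them into A) for the count test."""
    kept_positions = {pos for p, pos in kept if p == pid}
    out = []
    for i, ch in enumerate(seq):
        out.append("A" if ch == "K" and (i + 1) not in kept_positions else ch)
    return "".join(out)


class TestSampleRoundTrip:
    def test_tsv_round_trip(self, tmp_path, small_samples):
        path = tmp_path / "samples.tsv"
        write_samples(small_samples, path)
        assert read_samples(path) == small_samples


def test_normalize_sequence_rules():
    assert normalize_sequence("mkU*z") == "MKXXX"
    with pytest.raises(ValueError, match="position 2"):
        normalize_sequence("A1C")
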