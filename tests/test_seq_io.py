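"""FASTA I/O, ORF finding and table parsing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclomine import (
    AlphabetError,
    DuplicateIdError,
    FastaParseError,
    Transcript,
    ValidationError,
    find_orfs,
    read_expression,
    read_fasta,
    read_peaklist,
    write_fasta,
)
from cyclomine.seq_io import ProteinRecord, orf_translation, translate_nt

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# FASTA


def test_read_fasta_normalizes_case_and_strips_stop(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">x\nacgt\n")
    (t,) = read_fasta(p, "nt")
    assert (t.id, t.seq) == ("x", "ACGT")
    p.write_text(">y\nmkla*\n")
    (r,) = read_fasta(p, "aa")
    assert r.seq == "MKLA"


def test_read_fasta_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p, "nt") == []


def test_read_fasta_duplicate_id_error(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">a\nACGT\n>a\nACGT\n")
    with pytest.raises(DuplicateIdError):
        read_fasta(p, "nt")


def test_read_fasta_malformed_header(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text("ACGT\n>a\nACGT\n")
    with pytest.raises(FastaParseError):
        read_fasta(p, "nt")


def test_read_fasta_illegal_character_names_record(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">a\nACGU\n")
    with pytest.raises(AlphabetError, match="a"):
        read_fasta(p, "nt")


def test_write_fasta_wraps_lines(tmp_path):
    rec = ProteinRecord(id="long", seq="A" * 130)
    path = tmp_path / "out.fasta"
    write_fasta([rec], path, width=60)
    lines = path.read_text().splitlines()
    assert [len(l) for l in lines[1:]] == [60, 60, 10]


@given(
    st.lists(
        st.tuples(
            st.integers(0, 10**6),
            st.text(alphabet=AA, min_size=1, max_size=200),
        ),
        min_size=0,
        max_size=8,
        unique_by=lambda t: t[0],
    )
)
def test_fasta_round_trip_identity(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("fasta") / "rt.fasta"
    recs = [ProteinRecord(id=f"r{i}", seq=seq) for i, seq in records]
    write_fasta(recs, path)
    back = read_fasta(path, "aa")
    assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


# ---------------------------------------------------------------------------
# ORFs


def brute_force_orfs(t: Transcript, min_aa: int):
    """Independent enumeration: translate all 6 frames, split on stops."""
    from Bio.Seq import Seq

    found = set()
    L = len(t.seq)
    for frame in (1, 2, 3, -1, -2, -3):
        work = t.seq if frame > 0 else str(Seq(t.seq).reverse_complement())
        offset = abs(frame) - 1
        trimmed = work[offset : offset + (len(work) - offset) // 3 * 3]
        protein = str(Seq(trimmed).translate())
        pos = 0
        for seg in protein.split("*"):
            if len(seg) >= min_aa:
                ws, we = offset + 3 * pos, offset + 3 * (pos + len(seg))
                fs, fe = (ws, we) if frame > 0 else (L - we, L - ws)
                found.add((frame, fs, fe, seg))
            pos += len(seg) + 1
    return found


def test_short_sequence_has_no_orfs():
    assert find_orfs(Transcript(id="t", seq="ATGAAA"), min_aa=50) == []


def test_orf_length_threshold_boundary():
    # one exactly-49-aa open segment between stops
    body = "GCT" * 49
    t = Transcript(id="t", seq="TAA" + body + "TAA")
    assert [o for o in find_orfs(t, min_aa=50) if o.frame == 1] == []
    hits = [o for o in find_orfs(t, min_aa=49) if o.frame == 1 and o.kind == "open"]
    assert len(hits) == 1 and hits[0].seq == "A" * 49


def test_orfs_match_brute_force_enumeration(rng):
    for _ in range(10):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        t = Transcript(id="t", seq=seq)
        mine = {
            (o.frame, o.start, o.end, o.seq)
            for o in find_orfs(t, min_aa=20)
            if o.kind == "open"
        }
        assert mine == brute_force_orfs(t, 20)


def test_orf_coordinates_reproduce_translation(rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
    t = Transcript(id="t", seq=seq)
    for o in find_orfs(t, min_aa=20):
        assert orf_translation(t, o) == o.seq


def test_codon_with_n_translates_to_x():
    assert translate_nt("ATGANAGGG") == "MXG"


# ---------------------------------------------------------------------------
# peaks and expression


def test_peaklist_sorted_and_validated(tmp_path):
    p = tmp_path / "peaks.tsv"
    p.write_text("3110.4\n3072.4\n")
    pl = read_peaklist(p)
    assert pl.peaks == [3072.4, 3110.4]
    p.write_text("3110.4\n-2\n")
    with pytest.raises(ValidationError):
        read_peaklist(p)


def test_expression_validation(tmp_path):
    p = tmp_path / "tpm.tsv"
    p.write_text("gene\tleaf\tpod\ng1\t1.5\t2.0\ng2\t0\t7\n")
    df = read_expression(p)
    assert df.shape == (2, 2) and df.loc["g2", "pod"] == 7
    p.write_text("gene\tleaf\tpod\ng1\t1.5\tNA\n")
    with pytest.raises(ValidationError, match="g1"):
        read_expression(p)
    p.write_text("gene\tleaf\tpod\ng1\t1.5\t-2\n")
    with pytest.raises(ValidationError, match="pod"):
        read_expression(p)
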