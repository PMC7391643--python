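"""Precursor architecture parsing, loop decomposition, topology calls."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclomine import (
    NotAPrecursorError,
    ProteinRecord,
    annotate_precursor,
    classify_topology,
    extract_loops,
    parse_architecture,
)
from cyclomine.annotate import ArchitectureConfig, PrecursorAnnotation
from cyclomine.templates import ALBUMIN1A_CONSENSUS, TOPOLOGY_TEMPLATES

SIGNAL = "MALLIVAFLAVVLFTTEA"
MATURE_MOBIUS = TOPOLOGY_TEMPLATES["mobius"].mature("N")  # ...SWPVC..N
LINKER = "SLKAGTSGSL"
CTPP = "SVAKVLG"


def full_precursor(mature=MATURE_MOBIUS):
    return SIGNAL + mature + LINKER + ALBUMIN1A_CONSENSUS + CTPP


def test_full_length_regions_parse_exactly():
    p = ProteinRecord(id="p", seq=full_precursor())
    ann = parse_architecture(p)
    s, m = len(SIGNAL), len(MATURE_MOBIUS)
    assert ann.signal == (0, s)
    assert ann.mature == (s, s + m)
    assert ann.linker == (s + m, s + m + len(LINKER))
    assert ann.albumin1a == (s + m + len(LINKER), s + m + len(LINKER) + 50)
    assert ann.ctpp == (s + m + len(LINKER) + 50, len(p.seq))
    assert ann.has_5p and ann.has_3p and ann.cleavage_motif == "TEA"


def test_truncated_precursor_flags():
    # signal removed: mature still parsed, has_5p False
    p = ProteinRecord(id="p", seq=full_precursor()[len(SIGNAL) :])
    ann = parse_architecture(p)
    assert not ann.has_5p and ann.mature is not None and ann.has_3p
    # albumin removed: has_3p False
    p2 = ProteinRecord(id="p2", seq=SIGNAL + MATURE_MOBIUS + LINKER)
    ann2 = parse_architecture(p2)
    assert ann2.has_5p and not ann2.has_3p and ann2.albumin1a is None


def test_non_precursor_raises():
    with pytest.raises(NotAPrecursorError):
        parse_architecture(ProteinRecord(id="junk", seq="A" * 80))


def test_loop_extraction_matches_construction():
    spacers = dict(pre="GE", loop1="AAA", loop2="BBBB".replace("B", "V"),
                   loop3="DDDD", loop4="E", loop5="FFFF".replace("F", "P"),
                   tail="GG")
    mature = (spacers["pre"] + "C" + spacers["loop1"] + "C" + spacers["loop2"]
              + "C" + spacers["loop3"] + "C" + spacers["loop4"] + "C"
              + spacers["loop5"] + "C" + spacers["tail"] + "N")
    p = ProteinRecord(id="d", seq=mature)
    ann = PrecursorAnnotation(precursor_id="d", mature=(0, len(mature)))
    d = extract_loops(ann, p)
    assert d.loops[:5] == (spacers["loop1"], spacers["loop2"], spacers["loop3"],
                           spacers["loop4"], spacers["loop5"])
    assert d.loops[5] == spacers["tail"] + "N" + spacers["pre"]
    assert d.cyclization_residue == "N"
    assert d.reconstruct() == mature


def test_seven_cysteine_domain_is_unusual():
    mature = "GECTCAAACVVVVCDDDDCECPPPPCGGN"  # extra Cys in loop 1
    p = ProteinRecord(id="u", seq=mature)
    ann = PrecursorAnnotation(precursor_id="u", mature=(0, len(mature)))
    d = extract_loops(ann, p)
    assert len(d.cys_positions) == 7
    assert classify_topology(d) == "unusual"


@given(
    st.tuples(
        st.text(alphabet="GAVLIST", min_size=0, max_size=4),
        *[st.text(alphabet="GAVLISTEKRQ", min_size=1, max_size=8) for _ in range(5)],
        st.text(alphabet="GAVLIST", min_size=1, max_size=5),
    )
)
def test_loop_reconstruction_identity(parts):
    pre, l1, l2, l3, l4, l5, tail = parts
    mature = pre + "C" + l1 + "C" + l2 + "C" + l3 + "C" + l4 + "C" + l5 + "C" + tail + "N"
    p = ProteinRecord(id="d", seq=mature)
    ann = PrecursorAnnotation(precursor_id="d", mature=(0, len(mature)))
    d = extract_loops(ann, p)
    assert d.reconstruct() == mature


def test_topology_rules():
    base = dict(id="d", seq="X", cys_positions=tuple(range(6)))
    from cyclomine.annotate import CyclotideDomain

    mob = CyclotideDomain(**base, loops=("GET", "VGGT", "STPG", "T", "TIPA", "TRN"),
                          cyclization_residue="N")
    assert classify_topology(mob) == "mobius"
    acy = CyclotideDomain(**base, loops=("GET", "VGGT", "STPG", "T", "KVTA", "TR"),
                          cyclization_residue=None)
    assert classify_topology(acy) == "acyclic"
    hyb = CyclotideDomain(**base, loops=("GET", "VGGT", "STPG", "T", "SWTV", "TRN"),
                          cyclization_residue="N")
    assert classify_topology(hyb) == "hybrid"
    bra = CyclotideDomain(**base, loops=("AES", "VYIS", "TVTALLG", "S", "KVTA", "YRN"),
                          cyclization_residue="N")
    assert classify_topology(bra) == "bracelet"
    # no references and no rule fired
    assert classify_topology(hyb, refs=()) == "unclassified"


def test_classification_deterministic_and_total(small_study):
    cfg, transcripts, truths = small_study
    for t in truths:
        if t.is_decoy:
            continue
        ap1 = annotate_precursor(ProteinRecord(id=t.id, seq=t.protein_seq))
        ap2 = annotate_precursor(ProteinRecord(id=t.id, seq=t.protein_seq))
        assert ap1.domain.topology == ap2.domain.topology == t.topology
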