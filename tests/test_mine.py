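"""Mining: synthetic recovery, thresholds, dedup, novelty flags."""

import pytest

from cyclomine import (
    ProteinRecord,
    dedupe,
    default_patterns,
    flag_novel,
    mine_cyclotides,
)
from cyclomine.annotate import AnnotatedPrecursor, annotate_precursor
from cyclomine.mine import has_cys_cluster
from cyclomine.pipeline import run_discovery
from cyclomine.synthetic import _default_mining_refs


def test_synthetic_set_mined_exactly(small_study):
    """All true precursors recovered, no decoy passes (10 + 20 study)."""
    cfg, transcripts, truths = small_study
    res = run_discovery(transcripts)
    recovered = {ap.record.source_id for ap in res.annotated}
    true_ids = {t.id for t in truths if not t.is_decoy}
    assert recovered == true_ids


def test_refs_only_identical_orf_returned():
    orf = ProteinRecord(id="o1", seq="GLPVCGETCVGGTCNTPGCTCSWPVCTRN")
    ref = ProteinRecord(id="ref", seq=orf.seq)
    (cand,) = mine_cyclotides([orf], patterns=(), refs=[ref])
    assert cand.record.id == "o1" and "homology" in cand.provenance


def test_stringent_thresholds_with_unrelated_refs_yield_nothing():
    orf = ProteinRecord(id="o1", seq="GLPVCGETCVGGTCNTPGCTCSWPVCTRN")
    ref = ProteinRecord(id="ref", seq="MKLVINHEQWRLIATY")
    assert mine_cyclotides([orf], patterns=(), refs=[ref],
                           min_identity=100, min_coverage=100) == []


def test_empty_orf_list_and_missing_evidence():
    assert mine_cyclotides([], patterns=default_patterns()) == []
    with pytest.raises(ValueError):
        mine_cyclotides([], patterns=(), refs=())


def test_cys_cluster_rule():
    assert has_cys_cluster("CAACAACAACAAC" + "A" * 50 + "CC")  # 5 C in 13 aa
    assert not has_cys_cluster("C" + "A" * 41 + "CCCC")  # fifth Cys too far
    assert not has_cys_cluster("ACDEFG" * 4)  # only four cysteines


def _annotated(seq_id, protein):
    return annotate_precursor(ProteinRecord(id=seq_id, seq=protein))


def test_dedupe_same_domain_different_signal(small_study):
    cfg, transcripts, truths = small_study
    t = next(t for t in truths if not t.is_decoy)
    sig_a = "MALLIVAFLAVVLFTTEA"
    sig_b = "MWFAVILMAILVAFMVTEA"
    rest = t.protein_seq[t.regions["mature"][0] :]
    ap1 = _annotated("a", sig_a + rest)
    ap2 = _annotated("b", sig_b + rest)
    dd = dedupe([ap1, ap2])
    assert len(dd.precursors) == 2 and len(dd.domains) == 1
    assert sorted(dd.domain_map[dd.domains[0].seq]) == ["a", "b"]


def test_dedupe_identical_and_idempotent(small_study):
    cfg, transcripts, truths = small_study
    t = next(t for t in truths if not t.is_decoy)
    aps = [_annotated(f"r{i}", t.protein_seq) for i in range(4)]
    dd = dedupe(aps)
    assert len(dd.precursors) == 1 and len(dd.domains) == 1
    dd2 = dedupe(dd.precursors)
    assert len(dd2.precursors) == 1 and len(dd2.domains) == 1


def test_dedupe_counts_match_ground_truth(small_study):
    cfg, transcripts, truths = small_study
    res = run_discovery(transcripts)
    expected_proteins = len({t.protein_seq for t in truths if not t.is_decoy})
    expected_domains = len({t.mature_seq for t in truths if not t.is_decoy})
    assert res.summary["n_unique_precursors"] == expected_proteins
    assert res.summary["n_unique_domains"] == expected_domains


def test_novelty_exact_rotation_and_empty_refs(small_study):
    cfg, transcripts, truths = small_study
    t = next(t for t in truths if not t.is_decoy and t.topology == "mobius")
    ap = _annotated("d", t.protein_seq)
    dom = ap.domain
    # verbatim reference -> not novel
    ref = ProteinRecord(id="known", seq=dom.seq)
    assert flag_novel([dom], [ref]) == {"d": False}
    # rotated copy of a cyclic reference -> not novel (checked over all offsets)
    for k in range(1, len(dom.seq)):
        rot = ProteinRecord(id=f"rot{k}", seq=dom.seq[k:] + dom.seq[:k])
        assert flag_novel([dom], [rot])["d"] is False
    # empty reference set -> novel
    assert flag_novel([dom], []) == {"d": True}
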