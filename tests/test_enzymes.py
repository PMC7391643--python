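"""Enzyme rule annotation: AEP ligase/protease call, PDI motifs, ERO1 sites,
cyclophilin domain architecture."""

import pytest

from cyclomine import ProteinRecord, annotate_aep, annotate_cyp, annotate_ero1, annotate_pdi
from cyclomine.enzymes import (
    default_aep_reference,
    default_cld_reference,
    default_ero1_reference,
    default_trx_consensus,
    parse_prosite,
)

AEP_REF, AEP_SITES = default_aep_reference()
ERO_REF, ERO_SITES = default_ero1_reference()


def mutated(seq, pos, res):
    return seq[:pos] + res + seq[pos + 1 :]


# ---------------------------------------------------------------------------
# AEP


def test_aep_reference_is_ligase_like():
    ann = annotate_aep(AEP_REF)
    assert ann.triad_complete
    assert ann.call == "ligase_like"
    assert ann.gk[0] == "C"


def test_aep_gatekeeper_gly_or_ser_means_protease():
    for res in "GS":
        q = ProteinRecord(id="q", seq=mutated(AEP_REF.seq, AEP_SITES["lad1_2_gk"], res))
        assert annotate_aep(q).call == "protease_like"


def test_aep_mutations_make_call_ambiguous():
    # catalytic Cys lost: triad incomplete, never ligase_like
    q = ProteinRecord(id="q", seq=mutated(AEP_REF.seq, AEP_SITES["triad_cys"], "A"))
    ann = annotate_aep(q)
    assert not ann.triad_complete and ann.call == "ambiguous"
    # gatekeeper neither ligase- nor protease-diagnostic
    q2 = ProteinRecord(id="q2", seq=mutated(AEP_REF.seq, AEP_SITES["lad1_2_gk"], "K"))
    assert annotate_aep(q2).call == "ambiguous"
    # LAD2 first position not small
    q3 = ProteinRecord(id="q3", seq=mutated(AEP_REF.seq, AEP_SITES["lad2_1"], "W"))
    assert annotate_aep(q3).call == "ambiguous"


def test_aep_calls_mutually_exclusive(rng):
    # the decision rule cannot emit both calls for any gatekeeper residue
    for res in "ACDEFGHIKLMNPQRSTVWY":
        q = ProteinRecord(id="q", seq=mutated(AEP_REF.seq, AEP_SITES["lad1_2_gk"], res))
        ann = annotate_aep(q)
        assert ann.call in ("ligase_like", "protease_like", "ambiguous")
        if res in "GS":
            assert ann.call == "protease_like"
        elif res in "VICA":
            assert ann.call == "ligase_like"
        else:
            assert ann.call == "ambiguous"


# ---------------------------------------------------------------------------
# PDI


TRX = default_trx_consensus().seq


def _pdi_protein(motif_a="CGHC", motif_a2="CGHC", cterm="KDEL"):
    a = TRX[:30] + motif_a + TRX[34:]
    b = TRX
    b2 = TRX
    a2 = TRX[:30] + motif_a2 + TRX[34:]
    return "M" + a + b + b2 + a2 + "SG" + cterm


def test_pdi_classical_arrangement_and_kdel():
    ann = annotate_pdi(ProteinRecord(id="p", seq=_pdi_protein()))
    assert ann.arrangement == "a-b-b'-a'"
    assert [m for m, _pos in ann.active_sites] == ["CGHC", "CGHC"]
    assert ann.er_tetrapeptide == "KDEL" and ann.er_canonical


def test_pdi_non_canonical_retention_signal():
    ann = annotate_pdi(ProteinRecord(id="p", seq=_pdi_protein(cterm="KDQI")))
    assert ann.er_tetrapeptide == "KDQI" and not ann.er_canonical


def test_pdi_no_active_sites_on_unrelated_protein():
    ann = annotate_pdi(ProteinRecord(id="g", seq="G" * 120))
    assert ann.active_sites == [] and ann.arrangement == ""


# ---------------------------------------------------------------------------
# ERO1


def test_ero1_self_alignment_all_conserved():
    ann = annotate_ero1(ERO_REF)
    assert set(ann.conserved()) == set(ERO_SITES)


def test_ero1_serine_substitution_reported():
    pos = ERO_SITES["regulatory_4"]
    q = ProteinRecord(id="q", seq=mutated(ERO_REF.seq, pos, "S"))
    ann = annotate_ero1(q)
    site = next(s for s in ann.sites if s.name == "regulatory_4")
    assert site.status == "substituted" and site.residue == "S"


def test_ero1_unrelated_protein_mostly_unmapped():
    q = ProteinRecord(id="q", seq="GAVL" * 10)
    ann = annotate_ero1(q)
    conserved = [s for s in ann.sites if s.status == "conserved"]
    assert len(conserved) == 0


# ---------------------------------------------------------------------------
# CYP


CLD = default_cld_reference().seq


def test_cyp_reference_alone_is_single_domain():
    ann = annotate_cyp(ProteinRecord(id="c", seq=CLD))
    assert ann.cld is not None and not ann.multi_domain


def test_cyp_zinc_finger_flank_makes_multi_domain():
    zf = "AAC" + "GG" + "CTTTT" + "HSSSS" + "C"  # matches C-x(2)-C-x(4)-H-x(4)-C
    flank = zf + "KLVSTGRA" * 3
    ann = annotate_cyp(ProteinRecord(id="c", seq=flank + CLD))
    assert ann.cld is not None and ann.multi_domain
    assert "zf_CCHC_like" in ann.auxiliary_hits


def test_cyp_no_cld_no_call():
    ann = annotate_cyp(ProteinRecord(id="c", seq="MKLVSTGRAEDYW" * 6))
    assert ann.cld is None and not ann.multi_domain
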