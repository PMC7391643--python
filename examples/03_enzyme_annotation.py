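"""Rule-based annotation of cyclotide biosynthetic enzymes.

Maps functionally important residues through global alignments and applies
the ligase-activity rules for asparaginyl endopeptidases (AEP), the
CXXC/ER-retention motif rules for protein disulfide isomerases (PDI), the
conserved-cysteine map for ERO1 and the cyclophilin-like-domain (CLD)
architecture call for PPIases.
"""

from cyclomine import ProteinRecord, annotate_aep, annotate_ero1, annotate_pdi
from cyclomine.enzymes import default_aep_reference, default_trx_consensus

ref, sites = default_aep_reference()

# The bundled reference is ligase-type (aromatic LAD1 + Cys gatekeeper +
# small LAD2). Mutating the gatekeeper to Gly turns the call protease-like.
print("AEP calls:")
for label, gk_res in (("wild-type", None), ("GK->G mutant", "G")):
    seq = ref.seq
    if gk_res:
        pos = sites["lad1_2_gk"]
        seq = seq[:pos] + gk_res + seq[pos + 1 :]
    ann = annotate_aep(ProteinRecord(id=label, seq=seq))
    print(f"  {label}: call={ann.call} gatekeeper={ann.gk[0]} "
          f"triad_complete={ann.triad_complete}")

# A classical a-b-b'-a' PDI: two catalytic thioredoxin domains with CGHC
# active sites around two non-catalytic ones, ending in KDEL.
trx = default_trx_consensus().seq
a_dom = trx[:30] + "CGHC" + trx[34:]
pdi = ProteinRecord(id="pdi_demo", seq="M" + a_dom + trx + trx + a_dom + "SGKDEL")
ann = annotate_pdi(pdi)
print(f"\nPDI: arrangement={ann.arrangement} "
      f"active_sites={[m for m, _ in ann.active_sites]} "
      f"C-terminus={ann.er_tetrapeptide} ({'canonical' if ann.er_canonical else 'non-canonical'})")

# ERO1: every annotated reference cysteine is checked in the query.
from cyclomine.enzymes import default_ero1_reference

ero_ref, ero_sites = default_ero1_reference()
mutant = ero_ref.seq[: ero_sites["regulatory_4"]] + "S" + ero_ref.seq[ero_sites["regulatory_4"] + 1 :]
ann = annotate_ero1(ProteinRecord(id="ero_demo", seq=mutant))
for s in ann.sites:
    if s.status != "conserved":
        print(f"\nERO1: site {s.name} is {s.status} "
              f"({s.residue} at query position {s.query_position})")
# The single engineered Cys->Ser substitution is flagged; all other active,
# regulatory and structural cysteines map as conserved.
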