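"""Cysteine-anchored NJ phylogeny of mature cyclotide domains.

Builds mature domains from a synthetic study, aligns them on the conserved
six-cysteine framework, computes p-distances and reports a neighbor-joining
tree with bootstrap supports in Newick format.
"""

from cyclomine import (
    ProteinRecord,
    SimConfig,
    annotate_precursor,
    bootstrap,
    cys_anchor_align,
    generate_precursor_set,
)

cfg = SimConfig(seed=3, n_cyclotide=8, n_decoy=0, truncation_prob=0.0,
                domain_reuse_prob=0.0)
_, truths = generate_precursor_set(cfg)
domains = [annotate_precursor(ProteinRecord(id=t.id, seq=t.protein_seq)).domain
           for t in truths]

aln = cys_anchor_align(domains)
print(f"{len(aln.ids)} six-cysteine domains aligned over {aln.n_cols} columns")
print("first two rows:")
for row in aln.rows[:2]:
    print(" ", row)

tree = bootstrap(aln, n_reps=200, seed=1)
print("\nNJ tree with bootstrap supports (internal labels, %):")
print(tree.newick())
# Moebius/Hybrid domains (short loop 3) and Bracelet domains (long loop 3)
# fall into separate, well-supported parts of the tree.
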