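# cyclomine

Discovery and annotation of **cyclotide precursors** — and the enzymes that
make them — from plant transcriptome data.

Cyclotides are 26–37-residue plant peptides with a head-to-tail cyclic
backbone and a cyclic cystine knot (CCK: disulfides Cys I–IV, II–V, III–VI
threaded through the macrocycle). In Fabaceae such as *Clitoria ternatea*
("butterfly pea"), the cyclotide domain is embedded in an albumin-1-type
gene: ER signal peptide ending in the conserved Thr-Glu-Ala (TEA) cleavage
motif, the six-cysteine mature domain, a ~10-residue linker, a ~50-residue
albumin-1a chain and a short C-terminal propeptide. `cyclomine` implements
the full sequence-level analysis around this architecture:

* **seq_io** — FASTA/peak-list/TPM-table I/O and six-frame ORF extraction
  (open-segment and ATG-anchored variants, minimum 50 aa by default).
* **prosite / mine** — a PROSITE-syntax motif scanner plus Smith–Waterman
  homology search (BLOSUM62, gap open 11 / extend 1, identity ≥ 30 %,
  reference coverage ≥ 70 %), with an explicit auto-curation rule (≥ 5 Cys
  within a 40-residue window), deduplication (precursor vs unique mature
  domain) and novelty flagging (exact match or cyclic rotation against a
  reference set).
* **annotate** — precursor region parsing (signal/mature/linker/albumin-1a/
  CTPP), loop decomposition (loop *i* = residues between Cys *i* and
  Cys *i+1*; loop 6 spans the cyclization junction) and topology calls:
  *Möbius* (Pro in loop 5), *Bracelet*, *Hybrid* (Möbius-like loops 2–3
  without the loop-5 Pro), *acyclic* (no C-terminal Asn/Asp) and *unusual*
  (atypical cysteine framework).
* **masses** — monoisotopic/average masses of linear or cyclic, reduced or
  oxidized peptides (cyclization −H₂O; each disulfide −2 H) and matching
  against MALDI [M+H]⁺ peak lists.
* **enzymes** — rule annotation of asparaginyl endopeptidases (ligase vs
  protease call from the LAD1/LAD2/gatekeeper residues), protein disulfide
  isomerases (CXXC active sites, a/b domain arrangement, `[K/H/N][D/E]EL`
  ER-retention tetrapeptide), ERO1 (conserved cysteine map) and
  cyclophilins (single- vs multi-domain CLD architecture).
* **cluster** — Pearson-correlation distance (1 − *r*) with complete
  linkage over tissue TPM profiles.
* **phylo** — cysteine-anchored alignment of mature domains, p-distances,
  Saitou–Nei neighbor joining and bootstrap supports, Newick output.
* **synthetic** — a ground-truthed generator of precursor transcripts,
  decoys, peak lists and tissue-clustered TPM matrices, so every stage is
  testable without any downloads.

## Worked example

```python
from cyclomine import SimConfig, generate_precursor_set, run_discovery

cfg = SimConfig(seed=42, n_cyclotide=12, n_decoy=18, truncation_prob=0.0)
transcripts, truths = generate_precursor_set(cfg)
result = run_discovery(transcripts)
print(result.summary)
```

prints

```
{'n_transcripts': 30, 'n_orfs': 97, 'n_candidates': 12,
 'n_precursor_transcripts': 12, 'n_unique_precursors': 12,
 'n_unique_domains': 9, 'n_novel_domains': 9,
 'topology_tally': {'acyclic': 1, 'bracelet': 4, 'hybrid': 2, 'mobius': 2},
 'n_peak_matches': 0}
```

All 12 true precursors (and none of the 18 decoys) are mined; three
precursors are redundant copies of another mature domain behind a different
signal/albumin region, leaving 9 unique domains, all novel with respect to
the (empty) reference set. Mass prediction for a kalata-B1-like domain:

```python
from cyclomine import peptide_mass, compute_mh
seq = "GLPVCGETCVGGTCNTPGCTCSWPVCTRN"
peptide_mass(seq, cyclic=True, n_disulfides=3)   # 2890.1424 Da
compute_mh(3071.4, "unit")                       # 3072.4  (printed M+H style)
```

The `examples/` directory holds one short narrative script per capability
(discovery, mass matching, enzyme rules, expression clustering, phylogeny);
each prints the numbers it computes and a line on what they mean. The same
functionality is exposed as a thin CLI:

```bash
cyclomine pipeline --seed 7 --out run/
cyclomine tree --precursors precursors.fasta --bootstrap 1000 --seed 1 --out tree.nwk
```

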