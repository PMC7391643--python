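# Methods

This note records the models, rules and numerical choices behind
`cyclomine`, and what the synthetic-data experiments do and do not show.

## Precursor model

The package targets albumin-1-type cyclotide genes (Fabaceae "cliotides"):

```
[ER signal ... T E A][mature 6-Cys domain][linker ~10 aa][albumin-1a ~50 aa][CTPP]
```

Region boundaries are defined operationally, because only sequence is
observable:

* **Signal peptide** — from the protein start to the end of the *last* TEA
  motif occurring before the first cysteine cluster (signal peptidase-1
  cleaves after TEA). A missing TEA marks a 5′-truncated precursor
  (`has_5p = False`); the mature N-terminus then falls back to five
  residues before Cys I (configurable), which accommodates both novel
  N-terminal stretches and non-Gly start residues.
* **Cysteine cluster** — the first window holding ≥ 5 cysteines within
  40 residues; the framework is extended with further cysteines spaced
  ≤ 12 residues apart. Five tolerates truncated or atypical frameworks;
  40 is roomy for a 26–37-residue domain.
* **Mature C-terminus** — the first Asn/Asp within 12 residues after the
  last framework cysteine (the residue the cyclizing asparaginyl
  endopeptidase attacks), inclusive. When no Asn/Asp occurs in the window
  the domain is **acyclic** and the mature region ends a fixed 4 residues
  after Cys VI. That tail length is a convention, not biology: without the
  cyclization residue nothing in the sequence marks the processing site.
  The synthetic generator emits exactly this convention so that acyclic
  boundaries remain exactly recoverable.
* **Albumin-1a** — located by Smith–Waterman alignment against a bundled
  50-residue consensus (identity ≥ 55 %, consensus coverage ≥ 60 %). The
  consensus is a synthetic stand-in with the hallmark interior cysteine
  pair; in real analyses it would be replaced by a curated albumin-1a
  profile. The linker is whatever separates the mature region from the
  albumin-1a start (a warning is logged beyond 15 residues); the CTPP is
  everything after the albumin-1a end.

## Topology classification

Decision order (deterministic and total): **unusual** (cysteine count ≠ 6)
→ **acyclic** (no cyclization residue) → **mobius** (Pro anywhere in
loop 5 — a sequence-level proxy for the cis-Pro peptide bond, whose isomer
state is unobservable from sequence) → nearest-reference vote over loops 2
and 3 (ungapped positional identity, denominator the longer loop, averaged
over the two loops) against labeled reference domains: a Möbius-like best
label yields **hybrid**, otherwise **bracelet**; ties lean bracelet, the
majority subfamily. With no references and no rule fired the label is
**unclassified**. The Bracelet/Hybrid boundary is this package's explicit,
configurable stand-in for a decision the source analyses made by expert
inspection; the bundled references are the generator's own loop templates,
so users comparing real data should supply curated reference domains.
The conserved loop-1 Glu is reported as a boolean annotation only and never
filters.

## Mining

Candidates are the union of motif hits and homology hits, then auto-curated
by the ≥ 5-Cys/≤ 40-residue rule (a reproducible replacement for manual
inspection). The bundled motif patterns are synthetic stand-ins written in
PROSITE syntax for the six-cysteine framework (with loop-length bounds, a
loop-5-Pro variant and a long-loop-3 variant, plus a five-cysteine variant
for truncated/atypical frameworks); the scanner itself supports the full
pattern syntax and is oracle-checked against regex translation. Homology
uses Smith–Waterman with BLOSUM62, gap open 11 / extend 1 (BLAST-style gap
cost `open + extend·L`), identity ≥ 30 % over aligned columns (gaps
included) and coverage ≥ 70 % of the reference mature domain. Identity's
denominator (aligned columns including gaps) and coverage's (query length)
follow common BLAST reporting. Among co-optimal tracebacks the smallest
query start, then the shortest span, is reported.

Deduplication is two-level: precursors unique by full protein string,
domains unique by mature string, preserving the many-precursors→one-domain
map. Novelty means no exact reference match and, for cyclic domains, no
match to any cyclic rotation of a cyclic reference.

## Masses

Standard monoisotopic residue masses (six decimals; water 18.010565 Da,
H 1.0078250319 Da, proton 1.00728 Da). Linear reduced mass = residue sum +
water; head-to-tail cyclization −1 water; each disulfide −2 H. Mature
domains are matched fully oxidized (⌊nCys/2⌋ disulfides), cyclic when the
cyclization residue is present, linear otherwise — mature cyclotides are
oxidized in planta. Two [M+H]⁺ conventions: `proton` (+1.00728, default)
and `unit` (+1.0, matching how printed MALDI tables round "M + H" from an
m/z given to one decimal); printed tables are ambiguous between the two, so
both are exposed. Default matching tolerance 0.5 Da (peak lists printed to
one decimal); the peak-recovery experiments use 0.1 Da on noiseless data.

## Enzyme rules

* **AEP**: reference sites (catalytic Asn/His/Cys triad, LAD1 pair — the
  second position being the gatekeeper — LAD2 first position, MLA bounds)
  are mapped through a Needleman–Wunsch alignment. `ligase_like` requires a
  complete triad **and** LAD1₁ ∈ {F,Y,W} **and** gatekeeper ∈ {V,I,C,A}
  **and** LAD2₁ ∈ {G,A}; gatekeeper ∈ {G,S} gives `protease_like`;
  everything else is `ambiguous`. The two calls are mutually exclusive by
  construction. MLA length is reported as informational only — it sits far
  from the catalytic core and is deliberately excluded from the call.
* **PDI**: thioredoxin-fold segments are found by iterated local alignment
  against a bundled consensus (identity ≥ 40 %, coverage ≥ 60 %, aligned
  spans masked between rounds); segments containing C-x-x-C are catalytic
  (a-type). The arrangement string labels catalytic segments a, a′, a″ and
  non-catalytic b, b′, b″ in sequence order (classical PDIs read
  `a-b-b'-a'`). The C-terminal tetrapeptide is canonical when it matches
  `[KHN][DE]EL`; anything else (e.g. KDQI) is reported verbatim.
* **ERO1**: each annotated reference cysteine (outer/inner active pairs,
  regulatory set, long-range pair, PDI-interacting pair) maps through the
  global alignment and is reported conserved, substituted (with the
  residue) or absent. Site numbering lives in editable TSVs because it is
  alignment-relative, never absolute.
* **CYP**: the cyclophilin-like domain is located by local alignment to a
  reference CLD (identity ≥ 30 %, reference coverage ≥ 70 %); a flank of
  ≥ 20 residues matching a supplied auxiliary motif (default zinc-finger
  `C-x(2)-C-x(4)-H-x(4)-C`) upgrades the call to multi-domain.

The bundled reference sequences are deterministic synthetic scaffolds
(labelled `synthetic` in their filenames); they carry the right *site
grammar* for the rules and tests, not real enzyme sequences, and are meant
to be replaced by curated references for real analyses.

## Expression clustering

d(i,j) = 1 − Pearson r over per-gene profiles, complete linkage (scipy).
Profiles are centered and scaled per gene by default (heatmap convention;
correlation is scale-free, so this mainly guards downstream cut heights);
zero-variance genes are dropped with a warning. Replicate columns can be
averaged per tissue first. Agglomeration order and tie-breaking follow
scipy's deterministic implementation; complete linkage guarantees monotone
merge heights.

## Phylogeny

Six-cysteine domains are aligned by right-padding the seven loop blocks
(pre-Cys I, loops 1–5, post-Cys VI) to their per-block maxima, keeping the
framework cysteines in gap-free columns — a deliberate, assumption-light
alternative to progressive MSA that exploits the conserved framework.
Distances are p-distances with pairwise deletion (the default distance of
common NJ tools; model-based distances are out of scope, so exact
reproduction of published tree figures is not claimed). NJ is Saitou–Nei
with the standard Q criterion, smallest-index tie-break and negative branch
lengths clamped to zero; on additive matrices the reconstruction is exact
(verified on random trees). Bootstrap resamples columns with replacement;
support is the percentage of replicates containing each internal
bipartition of the point tree. Default 1000 replicates keeps desk-scale
runtimes (published analyses often use 10,000; it is a parameter). For an
alignment of identical sequences all distances are zero and supports are
reported on an arbitrary (tie-broken) resolution — degenerate by
construction.

## Synthetic generator

Defaults encode the observed composition of the *C. ternatea* cyclotide
repertoire: topology proportions 11/51 Möbius, 27/51 Bracelet, 8/51 Hybrid,
3/51 acyclic, 2/51 unusual (largest-remainder apportionment); truncation
probability 9/71; domain-reuse probability 20/71 (redundant precursors
sharing a mature domain); proteomic detection probability 30/51. Loop
templates follow the classification conventions (loop 1 = 3 residues with
the conserved Glu, loop 2 = 4, loop 3 ∈ [4,5] for Möbius/Hybrid vs [6,8]
for Bracelet, loop 4 = 1, loop 5 ∈ [4,5] with mandatory Pro for Möbius,
short loop-6 tail ending in Asn (90 %) or Asp); per-residue loop mutation
rate 0.15 and albumin interior mutation rate 0.08 are the package's
realism choices — high enough that domains are individually distinct, low
enough that subfamily signatures persist. Unusual frameworks insert an
extra loop-1 cysteine (7 Cys) or drop Cys IV (5 Cys). Peak noise defaults
to 0.05 Da (reflectron-MALDI scale) with 10 uniform decoy peaks kept
≥ 0.5 Da away from true masses; expression uses log-normal noise
(σ = 0.25) around dominant-tissue cluster centers over leaf/flower/pod/stem.

Mutation alphabets deliberately exclude Cys (framework count must stay
fixed), Pro (the loop-5 signature must not arise by chance), Asn/Asp (the
cyclization residue must stay unique after Cys VI) and Glu in pre-mature
positions (no spurious TEA). Nucleotide encoding uses uniform synonymous
codons (mining is protein-level, so codon bias is irrelevant) with
frame-matched stop codons flanking the CDS, so the designed protein equals
one open-segment ORF exactly. Two rejection-sampling guards keep the ground
truth exact: decoys are resampled until they fail the default mining rules,
and *encodings* are resampled until no off-design ORF (other frames,
reverse strand — where forward ACA/GCA trinucleotides read as Cys codons)
is mineable. All randomness flows from one seeded generator per call.

**What passing these experiments shows — and does not.** Recovery, boundary
and topology accuracies of 100 % certify the internal consistency of rules
and parser on data that *satisfies the model's assumptions*. Real
transcriptomes add assembly artifacts, sequencing error, diverged signal
peptides, non-consensus albumin chains and borderline topologies that the
generator does not emulate; on real data the same thresholds will trade
sensitivity against specificity rather than achieve both perfectly.

## Numerical and scale choices

Test and acceptance problem sizes (40 + 60 transcripts, 1000 random
peptides, 100 additive matrices of 4–8 taxa, 200 bootstrap replicates,
45–60 genes) are chosen as the smallest sizes at which every code path and
degenerate case is exercised; all complete in seconds on one CPU.
Alignment scores are cross-checked against an independent gap-run
enumeration oracle (itself validated against fully exhaustive path
enumeration on tiny instances); masses against an independently sourced
residue table (pyteomics) to 1e-4 Da. Distance matrices are symmetrized
and clipped to [0, 2] against floating-point drift; NJ Q-comparisons use a
1e-12 margin so ties resolve to the smallest index pair.
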