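"""Mine cyclotide precursors from a (synthetic) transcriptome.

Generates a ground-truthed set of 12 albumin-1-type cyclotide precursor
transcripts plus 18 decoys, runs six-frame ORF extraction, motif + homology
mining, architecture parsing and topology classification, and compares the
result with the generator's truth.
"""

from cyclomine import SimConfig, generate_precursor_set, run_discovery

cfg = SimConfig(seed=42, n_cyclotide=12, n_decoy=18, truncation_prob=0.0)
transcripts, truths = generate_precursor_set(cfg)
result = run_discovery(transcripts)

print("summary:")
for key, value in result.summary.items():
    print(f"  {key}: {value}")

truth_by_id = {t.id: t for t in truths}
correct = sum(
    ap.domain.topology == truth_by_id[ap.record.source_id].topology
    for ap in result.annotated
)
print(f"\ntopology calls correct: {correct}/{len(result.annotated)}")
print("\nfirst three annotated precursors:")
for ap in result.annotated[:3]:
    d = ap.domain
    print(f"  {ap.record.source_id}: topology={d.topology} "
          f"cyclization={d.cyclization_residue} loops={d.loops}")

# The summary counts mean: of 30 transcripts, every true precursor (and no
# decoy) was mined; unique domains < precursors because redundant precursors
# share a mature domain behind different signal/albumin regions.
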