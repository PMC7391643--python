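"""Predict cyclotide masses and match a MALDI peak list.

Computes the monoisotopic neutral mass and [M+H]+ of a kalata-B1-like
cyclic, fully oxidized domain (three disulfides), shows the unit-style
"M + H" convention used when reproducing printed MALDI tables, and matches
a small observed peak list at 0.5 Da tolerance.
"""

from cyclomine import PeakList, compute_mh, mass_record, match_peaks, peptide_mass

seq = "GLPVCGETCVGGTCNTPGCTCSWPVCTRN"  # 29 aa, 6 Cys

linear_reduced = peptide_mass(seq)
cyclic_oxidized = peptide_mass(seq, cyclic=True, n_disulfides=3)
print(f"linear reduced monoisotopic mass: {linear_reduced:.4f} Da")
print(f"cyclic 3-SS monoisotopic mass:    {cyclic_oxidized:.4f} Da")
print(f"cyclization removes one water:    "
      f"{peptide_mass(seq) - peptide_mass(seq, cyclic=True):.5f} Da")

# a spectrum printed as m/z 3071.4 reports "M + H = 3072.4" (unit style)
print(f"unit-style M+H of m/z 3071.4:     {compute_mh(3071.4, 'unit'):.1f}")

rec = mass_record("kalata_like", seq, cyclic=True)
peaks = PeakList(peaks=[rec.mh + 0.12, 3110.4], label="demo")
for m in match_peaks([rec], peaks, tol=0.5):
    print(f"peak {m.peak_mz:.4f} -> {m.peptide_id} (delta {m.delta:+.4f} Da)")
# Only the first peak is within tolerance of the predicted [M+H]+; the
# second stays unassigned, as an unrelated cyclotide mass should.
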