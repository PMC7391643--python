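# Synthetic stand-in motif patterns for the cyclotide cysteine framework.
# These are NOT the PROSITE accessions PS51052/PS60008/PS60009; they encode
# the same qualitative signatures (six-Cys framework with bounded loop
# lengths; loop-5 Pro for the Moebius subfamily; long loop 3 for Bracelets;
# a five-Cys variant tolerating truncated/atypical frameworks).
CYCLOTIDE_FRAMEWORK_6CYS	C-x(2,12)-C-x(2,12)-C-x(2,12)-C-x(1,12)-C-x(2,12)-C
CYCLOTIDE_BRACELET_LIKE	C-x(2,12)-C-x(2,12)-C-x(6,12)-C-x(1,12)-C-x(2,12)-C
CYCLOTIDE_MOBIUS_LIKE	C-x(2,12)-C-x(2,12)-C-x(2,12)-C-x(1,12)-C-x(1,4)-P-x(0,4)-C
CYCLOTIDE_FRAMEWORK_5CYS	C-x(2,12)-C-x(2,12)-C-x(2,12)-C-x(2,12)-C
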