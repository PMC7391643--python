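# synthetic ERO1 reference cysteine sites (0-based positions)
site	position
long_range_1	30
outer_1	40
outer_2	45
regulatory_3	50
regulatory_4	85
pdi_interact_1	110
pdi_interact_2	130
long_range_2	158
inner_1	165
inner_2	168
noncatalytic_1	190
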