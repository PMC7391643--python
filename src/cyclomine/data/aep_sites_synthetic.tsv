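# synthetic AEP reference site annotations (0-based positions)
site	position
triad_asn	60
triad_his	100
triad_cys	160
lad1_1	169
lad1_2_gk	170
lad2_1	185
mla_start	200
mla_end	216
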