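>aep_ref_synthetic synthetic ligase-type AEP scaffold
TMYSPKESTAWGMTGYDRMIAFQMMMHSIRQTDRSKKTTAHMRMEHFAAYTLSGMKWSAH
NTFYVYVKYFYTEQWLTGKWIAWYGFMYYWMGAWFESYWRHKYTQEFLVVIFAMEMSEEE
QIGYEFRWPVPLIYPPIYRSPRSYGYVTGYWKFEVYKILFCPYRWQMDEWCEWRQPPDER
DQQSAGIPKPYWAMIGIIGKLLHAQQIAAWRRPSAQQWEKLEAASMWVAWRGYHQFWVQK
VSIGGTYWPDIMIMQIKVFH
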