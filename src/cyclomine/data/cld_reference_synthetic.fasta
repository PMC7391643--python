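>cld_ref_synthetic synthetic cyclophilin-like domain
GYTKQIIVWQGEPDTAEMQAHPHGGKYDRKSQWAVTYFHMMGLRFAEEPQMTKTLWAMIL
AQVEIDDWPFSYTQAIHAHPPDSQHSRTRAARPGGIPRRMLWTQQSVVKQAMHKWKPSQI
RMHRQAGASQGWFEKDVEKHIDRHYIDPPT
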