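>ero1_ref_synthetic synthetic ER-oxidoreductin scaffold
GQQTKREPKAFIKDRKFQAQGPLVIQPWVVCAPGSTILHTCAAKACHKQVCLAEVSRVWE
RSAFTMESVITWRVLVMVMFRGQDMCDPAERKKPHVEGQVDMPSFVEYRYCWRGHWGIPG
EQLEGIDIDYCYQSDMYDWWMHAHFSGEQPGHLKLRHPCEMIWVTCQYCPMIEYYAQGHQ
SGWQMSMDDTCMDIKYDASVPEDSQETYPKMYKAWGQAKV
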