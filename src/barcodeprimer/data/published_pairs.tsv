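pair_name	forward_name	forward_seq	reverse_name	reverse_seq
30F/885R	30F	HACTAATCAYAARGATATTGGWAC	885R	RAACATATGATGAGCYCAWACAAT
LCO2198/HCO1490	LCO2198	GGTCAACAAATCATAAAGATATTGG	HCO1490	TAAACTTCAGGGTGACCAAAAAATCA
dgLCO/dgHCO	dgLCO	GGTCAACAAATCATAAAGAYATYGG	dgHCO	TAAACTTCAGGGTGACCAAARAAYCA
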