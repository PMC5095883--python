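patient	position	compartment	depth	allele1	freq1_pct	allele2	freq2_pct
1	11836	plasma	56	A	92.9	G	7.1
1	11836	wbc	3714	A	99.54	G	0.46
93	16111	plasma	58	T	93.10	C	6.90
93	16111	wbc	2663	T	99.74	C	0.26
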