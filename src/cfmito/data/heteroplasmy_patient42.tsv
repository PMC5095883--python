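position	compartment	depth	allele1	freq1_pct	allele2	freq2_pct
186	plasma	481	T	2.1	G	97.9
186	wbc	2325	T	0.13	G	99.87
207	plasma	335	A	1.8	G	98.2
207	wbc	2040	A	96.8	G	3.2
8425	plasma	46	A	19.6	G	80.4
8425	wbc	3352	A	99.9	G	0.1
12127	plasma	193	A	92.7	G	7.3
12127	wbc	5602	A	0.4	G	99.6
13708	plasma	709	A	0.3	G	99.7
13708	wbc	2015	A	96.7	G	3.2
14364	plasma	870	A	0.7	G	99.2
14364	wbc	4353	A	95.6	G	4.4
16126	plasma	264	T	17.0	C	83.0
16126	wbc	7077	T	99.8	C	0.2
16129	plasma	157	A	72.0	G	27.4
16129	wbc	6878	A	1.2	G	98.7
477	plasma	452	T	100	C	0
477	wbc	942	T	96.1	C	3.9
3010	plasma	865	A	0	G	100
3010	wbc	7087	A	2.2	G	97.8
14350	plasma	667	T	0	C	100
14350	wbc	4788	T	2.5	C	97.5
72	plasma	1199	T	84.8	C	15.1
72	wbc	2325	T	100	C	0
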