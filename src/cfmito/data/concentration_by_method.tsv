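sample	standard	optimized	optimized_ss
1	0.00332	0.02114	0.17842
2	0.00307	0.01428	0.05366
17	0.00543	0.01310	0.15901
42	0.05152	0.92133	2.75686
69	0.00188	0.00688	0.10392
78	0.00114	0.01044	0.14689
93	0.00237	0.01256	0.20437
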