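class	n_active	pairwise_similarity
09249	900	0.111
12455	1400	0.098
12464	505	0.102
31281	106	0.125
43210	957	0.119
71522	700	0.103
75721	636	0.110
78331	636	0.108
78348	617	0.123
78351	2111	0.113
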