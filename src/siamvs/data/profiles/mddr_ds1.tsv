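class	n_active	pairwise_similarity
31420	1130	0.290
71523	750	0.198
37110	803	0.180
31432	943	0.229
42731	1246	0.149
06233	752	0.140
06245	359	0.122
07701	395	0.138
06235	827	0.133
78374	453	0.120
78331	636	0.108
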