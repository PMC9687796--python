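class	n_active	pairwise_similarity
07707	207	0.229
07708	156	0.305
31420	1130	0.290
42710	111	0.361
64100	1346	0.336
64200	113	0.322
64220	1051	0.269
64500	126	0.260
64350	388	0.305
75755	455	0.386
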