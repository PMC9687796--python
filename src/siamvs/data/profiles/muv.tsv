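class	n_active	pairwise_similarity
466	30	0.117
644	30	0.122
600	30	0.123
689	30	0.113
652	30	0.099
712	30	0.106
692	30	0.114
733	30	0.114
713	30	0.113
810	30	0.107
737	30	0.129
846	30	0.161
832	30	0.151
858	30	0.111
852	30	0.150
548	30	0.128
859	30	0.126
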