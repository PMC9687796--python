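class	TAN	BIN	SQB	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
466	3.1	6.33	1.38	6	6.67	4.33	4.00	4.00	3.00
548	8.62	14.89	11.38	13.33	28.67	18.00	23.33	26.00	23.67
600	3.79	6.33	5.52	5.33	14.67	7.33	7.00	8.33	9.00
644	7.59	11	8.97	15.33	14.67	20.33	20.67	23.67	20.00
652	2.76	7	3.79	5.33	12.00	4.33	8.67	8.67	8.33
689	3.79	7.33	4.48	3.67	8.00	5.00	7.67	7.67	8.00
692	0.69	5.33	1.38	3	6.67	3.33	3.33	3.33	3.67
712	4.14	8.22	5.17	10.67	8.67	4.00	6.67	7.00	7.00
713	3.1	5.89	2.76	4.67	6.00	3.67	4.67	5.33	4.33
733	3.45	6.67	4.14	3.67	6.00	4.00	5.33	5.00	4.67
737	2.41	5.11	1.72	6.33	7.33	3.00	4.00	5.00	4.67
810	2.07	6.78	1.72	4.67	6.67	4.33	3.67	3.33	3.00
832	6.55	12.55	8.28	21.33	16.67	8.00	16.00	18.33	17.00
846	9.66	13.11	12.41	26.33	16.00	13.33	17.00	18.00	16.33
852	12.41	13.78	9.66	33	18.00	18.33	23.00	25.00	21.00
858	1.72	5.11	1.38	3	7.33	3.67	4.00	3.33	3.67
859	1.38	4.89	2.41	4.33	6.67	4.33	3.67	3.33	3.00
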