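class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
31420	83.49	87.61	87.22	89.03	87.35	90.82	87.55	87.58	90.43	94.06
71523	48.92	52.72	48.7	65.17	79.61	79.48	79.51	80.65	83.44	86.44
37110	21.01	48.2	45.62	41.25	76	73.91	76.55	75.56	81.71	84.54
31432	74.29	77.57	70.44	79.87	91.83	93.87	93.81	92.26	95.23	95.02
42731	29.68	26.63	24.35	31.92	57.52	61.06	61.2	62.53	69.74	77.27
06233	27.68	23.49	20.04	29.31	62.76	53.57	62.67	64.21	75.23	80.2
06245	16.54	14.86	13.72	21.06	28.9	20.9	27.94	28.54	34.79	39.35
07701	24.09	27.79	26.73	28.43	42.25	38.33	38.43	39.82	46.68	49.65
06235	20.06	23.78	22.81	27.82	40.36	35.98	39.93	37.3	51.65	53.21
78374	20.51	20.2	19.56	19.09	48.27	48.4	49.44	47.78	55.27	57.82
78331	16.2	11.8	11.37	16.21	25.02	22.65	27.23	26.77	35.06	39.69
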