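class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
31420	69.69	74.08	73.73	74.21	84.58	84.19	84.22	83.88	86.94	88.28
71523	25.94	28.26	26.84	27.97	59.41	61.25	60.53	61.48	59.02	66.45
37110	9.63	26.05	24.73	26.03	52.88	46.56	52.94	50.28	46.42	58.13
31432	35.82	39.23	36.66	39.79	66.41	64.19	68.33	68.18	78.8	69.72
42731	17.77	21.68	21.17	23.06	38.88	42.69	42.19	42.81	34.02	55.45
06233	13.87	14.06	12.49	19.29	35.03	23.87	33.36	35.64	32.66	47.93
06245	6.51	6.31	6.03	6.27	10.68	6.79	10.9	10.85	19.02	16.25
07701	8.63	11.45	11.35	14.05	16.96	14.78	14.89	14.86	29.86	22.03
06235	9.71	10.84	10.15	12.87	15.31	12.82	16.32	14.29	26.97	23.58
78374	13.69	14.25	13.08	17.47	24.6	21.78	24.67	24.31	25.53	25.89
78331	7.17	6.03	5.92	9.93	8.58	5.94	8.69	8.44	16.12	14
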