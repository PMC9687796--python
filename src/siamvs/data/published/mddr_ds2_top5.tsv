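class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
07707	70.39	74.81	74.37	73.9	95.85	85.17	89.9	94.83	88.29	87.17
07708	56.58	99.61	99.61	98.22	94.9	92.45	93.74	95.61	93.48	93.94
31420	88.19	95.46	94.88	95.64	94.12	94.42	95.82	95.72	95.49	94.89
42710	88.09	92.55	91.09	90.12	85.64	84.18	87.82	85.45	86.91	85.64
64100	93.75	99.22	99.03	99.05	98.93	94.21	98.58	98.39	95.92	96.41
64200	77.68	99.2	99.38	93.76	86.19	61.48	74	85.61	63.48	70.58
64220	52.19	91.32	90.62	96.01	94.07	92.62	89.93	94.04	93.72	94.28
64500	44.8	94.96	92.48	91.51	73.2	71.68	71.04	73.84	73.76	74.16
64350	91.71	91.47	90.78	86.94	90.7	89.58	92.26	90.7	90.6	90.65
75755	94.82	98.35	98.37	91.6	90.99	90.86	90.84	90.99	90.95	90.99
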