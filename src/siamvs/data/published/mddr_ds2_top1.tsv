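class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
07707	61.84	72.18	72.09	83.19	93.27	77.32	88.2	91.8	83.46	83.61
07708	47.03	96	95.68	94.82	94.84	89.94	93.16	94.9	92.32	93.1
31420	65.1	79.82	78.56	79.27	76.96	80.66	80.02	80.64	78.93	77.35
42710	81.27	76.27	76.82	74.81	84.55	80.55	85.82	84.73	84.45	84.91
64100	80.31	88.43	87.8	93.65	97.63	89.33	96.47	95.66	91.73	93.22
64200	53.84	70.18	70.18	71.16	78.65	54.26	65.87	77.35	55.94	60.39
64220	38.64	68.32	67.58	68.71	90.81	87.91	82.62	90.53	92.29	92.34
64500	30.56	81.2	79.2	75.62	71.92	69.68	68.56	72.4	72.56	73.2
64350	80.18	81.89	81.68	85.21	87.32	83.66	85.27	88.34	84.99	85.06
75755	87.56	98.06	98.02	96.52	90.95	89.65	90.53	90.99	90.9	90.99
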