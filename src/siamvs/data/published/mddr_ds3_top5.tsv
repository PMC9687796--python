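class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
09249	24.17	25.72	17.8	31.61	61.84	68.2	62.47778	71.52222	75.03	67.78
12455	10.29	14.65	11.42	16.29	32.97	38.59	34.05	41.58572	46.95	47.07
12464	15.22	16.55	16.79	20.9	46.12	51.01	47.70298	56.37622	60.95	80.2
31281	29.62	28.29	29.05	36.13	78.57	74.76	74.09524	73.14286	72.67	88.57
43210	16.07	14.41	14.12	22.09	54.47	53.08	52.09424	56.50262	62.08	51.15
71522	12.37	8.44	13.82	14.68	29.19	24.57	23.62858	30.95714	37.27	31.36
75721	25.21	30.02	30.61	41.07	77.31	80.99	76.6614	81.44882	83.46	98.66
78331	15.01	12.03	11.97	17.13	31.29	31.17	31.52754	35.32284	36.93	42.36
78348	24.67	20.76	21.14	26.93	31.89	37.33	35.51222	33.43086	38.41	47.8
78351	11.71	12.94	13.3	17.87	30.16	36.2	30.95734	40.02844	41.2	37.89
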