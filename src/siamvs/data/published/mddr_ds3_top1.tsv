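class	TAN	BIN	SQB	SDBN	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
09249	12.12	15.33	10.99	19.47	38.01	43.06	38.53334	41.16666	45.12	42.19
12455	6.57	9.37	7.03	13.29	14.21	17.22	16.24286	18.37856	23.09	23.26
12464	8.17	8.45	6.92	12.91	25.98	29.13	26.79208	31.94058	37.31	41.33
31281	16.95	18.29	18.67	23.62	67.52	66.57	65.52382	64.7619	66.76	68.38
43210	6.27	7.34	6.83	14.23	29.34	28.08	28.78536	28.37696	36.05	37.35
71522	3.75	4.08	6.57	11.92	12	8.71	9.08571	10.985706	14.7	15.43
75721	17.32	20.41	20.38	29.08	52.11	52.83	50.48818	51.73228	54.43	56.06
78331	6.31	7.51	6.16	11.93	12.41	12.65	12.56694	12.125994	14.96	16.65
78348	10.15	9.79	8.99	9.17	13.85	18.18	15.999974	13.512192	14.33	15.79
78351	9.84	13.68	12.5	18.13	10.71	14.34	11.715648	14.8673	16.68	16.42
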