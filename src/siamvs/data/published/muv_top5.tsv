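class	TAN	BIN	SQB	SCNN1D	SMLP	Hybrid-D-Max2	Hybrid-D-Max3	Hybrid-F-Sum	Hybrid-F-Max
466	5.86	10.44	8.62	11	12.00	10.00	8.33	7.00	8.33
548	22.76	27.22	24.14	32	46.67	37.33	45.00	49.67	49.00
600	11.38	12.89	16.21	9.67	20.67	15.00	16.67	17.67	17.33
644	17.59	19.67	17.93	36.67	25.33	32.00	37.67	40.33	40.33
652	7.93	11.67	9.66	9.33	17.33	11.00	14.33	13.67	13.00
689	9.66	13.22	11.72	14	15.33	10.33	14.67	19.00	16.33
692	4.83	9.22	4.83	6	14.67	7.33	7.00	7.00	7.33
712	10.34	16.45	11.03	16.67	14.00	8.33	19.00	17.00	17.33
713	7.24	9	5.86	7.33	12.00	9.33	11.67	11.33	12.00
733	8.97	10.11	8.62	6.33	9.33	9.33	8.33	8.33	9.00
737	8.28	12	8.28	8.33	12.00	7.00	8.33	7.33	7.00
810	6.9	13.33	11.03	6.67	10.00	7.00	7.00	5.67	8.33
832	13.1	20.44	14.83	32	24.67	16.67	22.67	25.67	24.67
846	28.62	26.11	26.9	47	36.67	31.00	40.00	39.00	36.33
852	21.38	23.11	20	42.33	34.67	29.33	36.00	37.00	34.00
858	5.86	9.11	6.21	5	14.00	7.67	8.67	7.67	9.00
859	8.97	9.44	8.62	11.67	11.33	11.67	10.33	12.00	11.33
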