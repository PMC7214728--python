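site_id	predicted_cm	predicted_d_cm	n_seeds	n_recombinants	observed_d_cm
TS50	50.95	0.55	2688	15	0.56
TS41	51.27	0.23	2016	5	0.25
TS71	51.32	0.18	2079	3	0.14
TS72	51.33	0.17	1481	0	0.00
TS84	51.68	0.18	1153	4	0.35
TS75	51.68	0.18	1932	7	0.36
TS76	51.69	0.19	1587	2	0.13
TS78	51.75	0.25	1001	4	0.40
TS86	52.54	1.04	1291	9	0.70
TS8	52.56	1.06	1748	15	0.86
TS43	52.80	1.30	3578	36	1.01
TS11	53.15	1.65	1721	22	1.28
TS87	53.57	2.07	2261	53	2.34
TS45	53.66	2.16	1509	36	2.39
TS10	54.56	3.06	1913	55	2.88
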