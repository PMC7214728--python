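site_id	cm	n_regenerated	n_modified	n_hdr1_5p	n_hdr1_3p	n_2xhdr
TS49	50.87	214	198	2	4	3
TS50	50.95	263	218	4	8	8
TS51	51.06	300	280	4	5	11
TS41	51.27	356	220	7	7	11
TS71	51.32	979	871	25	13	59
TS72	51.33	309	287	7	4	7
TS81	51.45	220	170	3	6	6
TS73	51.48	252	191	1	4	7
TS14	51.54	293	277	4	3	2
TS74	51.61	161	129	1	4	1
TS75	51.68	899	716	4	6	15
TS84	51.68	366	273	6	7	6
TS76	51.69	264	198	3	5	18
TS77	51.72	666	502	8	7	14
TS78	51.75	329	188	1	1	7
TS19	51.95	217	17	0	1	0
TS85	51.95	217	168	1	3	1
TS86	52.54	216	183	1	1	6
TS8	52.56	217	205	2	2	9
TS43	52.8	179	140	1	5	3
TS11	53.15	177	174	2	6	7
TS47	53.21	200	171	1	2	7
TS80	53.23	336	330	3	1	4
TS52	53.25	222	151	0	2	0
TS87	53.57	302	298	6	2	12
TS88	53.59	370	193	3	2	1
TS45	53.66	616	562	16	10	36
TS44	54.16	246	221	0	1	9
TS46	54.43	244	220	7	0	5
TS10	54.56	224	209	4	4	4
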