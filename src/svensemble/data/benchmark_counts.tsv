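dataset	callset	svtype	total	tp	fp	fn	recall	precision	f1
HG002	DRAGEN	DEL	4787	3425	1362	2039	0.63	0.72	0.67
HG002	Manta	DEL	3935	2996	939	2468	0.55	0.76	0.64
HG002	DELLY	DEL	4142	2620	1522	2844	0.48	0.63	0.55
HG002	GRIDSS	DEL	2681	2299	382	3165	0.42	0.86	0.56
HG002	LUMPY	DEL	1528	668	860	4796	0.12	0.44	0.19
HG002	SvABA	DEL	1910	1526	384	3938	0.28	0.80	0.41
HG002	DRAGEN	INS	3403	2426	977	4855	0.36	0.71	0.45
HG002	Manta	INS	1800	1387	413	5894	0.19	0.77	0.31
HG002	DELLY	INS	155	142	13	7139	0.02	0.92	0.04
HG002	GRIDSS	INS	90	85	5	7196	0.01	0.94	0.02
HG00514	DRAGEN	DEL	6403	4790	1613	3739	0.56	0.75	0.64
HG00514	Manta	DEL	4183	3710	473	4819	0.44	0.89	0.58
HG00514	DELLY	DEL	4359	2996	1363	5533	0.35	0.69	0.46
HG00514	GRIDSS	DEL	2718	2582	136	5947	0.30	0.95	0.46
HG00514	LUMPY	DEL	4053	2798	1255	5731	0.33	0.69	0.44
HG00514	SvABA	DEL	1981	1668	313	6861	0.20	0.84	0.32
HG00514	DRAGEN	INS	5100	4654	446	7679	0.38	0.91	0.53
HG00514	Manta	INS	2291	2204	87	10129	0.18	0.96	0.30
HG00514	DELLY	INS	128	126	2	12207	0.01	0.98	0.02
HG00514	GRIDSS	INS	90	88	2	12245	0.01	0.98	0.01
HG00733	DRAGEN	DEL	5895	4896	999	3798	0.56	0.83	0.67
HG00733	Manta	DEL	4232	3749	483	4945	0.43	0.89	0.58
HG00733	DELLY	DEL	4574	3075	1499	5619	0.35	0.67	0.46
HG00733	GRIDSS	DEL	2655	2512	143	6182	0.29	0.95	0.44
HG00733	LUMPY	DEL	4170	2843	1327	5851	0.33	0.68	0.44
HG00733	SvABA	DEL	1944	1634	310	7060	0.19	0.84	0.31
HG00733	DRAGEN	INS	5313	4868	445	7627	0.39	0.92	0.55
HG00733	Manta	INS	2312	2236	76	10259	0.18	0.97	0.30
HG00733	DELLY	INS	130	129	1	12366	0.01	0.99	0.02
HG00733	GRIDSS	INS	81	80	1	12415	0.01	0.99	0.01
NA19240	DRAGEN	DEL	6897	5775	1122	4390	0.57	0.84	0.68
NA19240	Manta	DEL	4955	4423	532	5742	0.44	0.89	0.59
NA19240	DELLY	DEL	5061	3649	1412	6516	0.36	0.72	0.48
NA19240	GRIDSS	DEL	3098	2957	141	7208	0.29	0.95	0.45
NA19240	LUMPY	DEL	4608	3354	1254	6811	0.33	0.73	0.45
NA19240	SvABA	DEL	2283	2001	282	8164	0.20	0.88	0.32
NA19240	DRAGEN	INS	6144	5574	570	8579	0.39	0.91	0.55
NA19240	Manta	INS	2488	2375	113	11778	0.17	0.95	0.29
NA19240	DELLY	INS	134	129	5	14024	0.01	0.96	0.02
NA19240	GRIDSS	INS	72	70	2	14083	0.00	0.97	0.01
HG002	III-multiple agreement	DEL	3087	2554	533	2910	0.47	0.83	0.60
HG002	V-multiple agreement	DEL	3565	2638	927	2826	0.48	0.74	0.58
HG002	III-union	DEL	5353	3380	1973	2084	0.62	0.63	0.62
HG002	V-union	DEL	5605	3406	2199	2058	0.62	0.61	0.62
HG002	III-multiple agreement	INS	162	150	12	7131	0.02	0.93	0.04
HG002	V-multiple agreement	INS	162	150	12	7131	0.02	0.93	0.04
HG002	III-union	INS	1799	1387	412	5894	0.19	0.77	0.31
HG002	V-union	INS	1799	1387	412	5894	0.19	0.77	0.31
HG00514	III-multiple agreement	DEL	3125	2886	239	5643	0.34	0.92	0.50
HG00514	V-multiple agreement	DEL	3988	3130	858	5399	0.37	0.78	0.50
HG00514	III-union	DEL	5842	4269	1573	4260	0.50	0.73	0.59
HG00514	V-union	DEL	6234	4340	1894	4189	0.51	0.70	0.59
HG00514	III-multiple agreement	INS	132	129	3	12204	0.01	0.98	0.02
HG00514	V-multiple agreement	INS	132	129	3	12204	0.01	0.98	0.02
HG00514	III-union	INS	2277	2190	87	10143	0.18	0.96	0.30
HG00514	V-union	INS	2277	2190	87	10143	0.18	0.96	0.30
HG00733	III-multiple agreement	DEL	3154	2894	260	5800	0.33	0.92	0.49
HG00733	V-multiple agreement	DEL	4043	3158	885	5536	0.36	0.78	0.50
HG00733	III-union	DEL	6013	4336	1677	4358	0.50	0.72	0.59
HG00733	V-union	DEL	6426	4413	2013	4281	0.51	0.69	0.58
HG00733	III-multiple agreement	INS	136	135	1	12360	0.01	0.99	0.02
HG00733	V-multiple agreement	INS	136	135	1	12360	0.01	0.99	0.02
HG00733	III-union	INS	2293	2218	75	10277	0.18	0.97	0.30
HG00733	V-union	INS	2293	2218	75	10277	0.18	0.97	0.30
NA19240	III-multiple agreement	DEL	3694	3418	276	6747	0.34	0.93	0.49
NA19240	V-multiple agreement	DEL	4594	3723	871	6442	0.37	0.81	0.50
NA19240	III-union	DEL	6751	5102	1649	5063	0.50	0.76	0.60
NA19240	V-union	DEL	7100	5176	1924	4989	0.51	0.73	0.60
NA19240	III-multiple agreement	INS	135	131	4	14022	0.01	0.97	0.02
NA19240	V-multiple agreement	INS	135	131	4	14022	0.01	0.97	0.02
NA19240	III-union	INS	2481	2366	115	11787	0.17	0.95	0.28
NA19240	V-union	INS	2481	2366	115	11787	0.17	0.95	0.28
combined	DRAGEN	DEL	23982	18886	5096	13966	0.57	0.79	0.66
combined	Manta	DEL	17305	14878	2427	17974	0.45	0.86	0.59
combined	DELLY	DEL	18136	12340	5796	20512	0.38	0.68	0.48
combined	GRIDSS	DEL	11152	10350	802	22502	0.32	0.93	0.47
combined	LUMPY	DEL	14359	9663	4696	23189	0.29	0.67	0.41
combined	SvABA	DEL	8118	6829	1289	26023	0.21	0.84	0.33
combined	III-multiple agreement	DEL	13060	11752	1308	21100	0.36	0.90	0.51
combined	V-multiple agreement	DEL	16190	12649	3541	20203	0.39	0.78	0.52
combined	III-union	DEL	23959	17087	6872	15765	0.52	0.71	0.60
combined	V-union	DEL	25365	17335	8030	15517	0.53	0.68	0.60
combined	DRAGEN	INS	19960	17522	2438	28740	0.38	0.88	0.53
combined	Manta	INS	8891	8202	689	38060	0.18	0.92	0.30
combined	DELLY	INS	547	526	21	45736	0.01	0.96	0.02
combined	GRIDSS	INS	333	323	10	45939	0.01	0.97	0.01
combined	III-multiple agreement	INS	565	545	20	45717	0.01	0.96	0.02
combined	V-multiple agreement	INS	565	545	20	45717	0.01	0.96	0.02
combined	III-union	INS	8850	8161	689	38101	0.18	0.92	0.30
combined	V-union	INS	8850	8161	689	38101	0.18	0.92	0.30
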