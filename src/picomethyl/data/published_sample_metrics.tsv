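sample	day	treatment	replicate	read_pairs	mapping_efficiency_pct	unique_cpgs	coverage	median_cov_cpg	median_cov_chg	median_cov_chh	called_cpg	called_chg	called_chh	frac_cpg	frac_chg	frac_chh
Day 4 Control 1	4	control	1	41023876	75	972932	73	62	57	40	944940	1228396	3846923	0.123	0.008	0.009
Day 4 Control 2	4	control	2	33648831	77	973618	63	81	78	59	942047	1223285	3817927	0.122	0.006	0.007
Day 4 Control 3	4	control	3	29579086	76	973104	53	44	41	28	928325	1202508	3674044	0.121	0.005	0.007
Day 5 Control 1	5	control	1	25654725	77	973344	54	47	45	33	937428	1219080	3780033	0.123	0.008	0.010
Day 5 Control 2	5	control	2	29937985	79	971660	54	44	40	26	910613	1176724	3483664	0.126	0.005	0.007
Day 5 Control 3	5	control	3	45111988	77	975224	92	52	48	33	964233	1257465	4098185	0.123	0.010	0.013
Day 6 Control 1	6	control	1	36639600	80	973029	69	58	54	37	938805	1219379	3782740	0.123	0.005	0.007
Day 6 Control 2	6	control	2	40794105	74	972768	74	63	59	41	943226	1226052	3830516	0.122	0.007	0.009
Day 6 Control 3	6	control	3	29191188	74	972574	52	43	40	26	916792	1186033	3549572	0.123	0.006	0.007
Day 7 Control 1	7	control	1	33885815	77	972102	61	52	47	33	934725	1212452	3731159	0.123	0.007	0.009
Day 7 Control 2	7	control	2	40610069	72	972679	66	54	49	35	941356	1221066	3827818	0.120	0.007	0.008
Day 7 Control 3	7	control	3	26226738	77	972111	50	44	41	30	931596	1209022	3711732	0.119	0.007	0.008
Day 10 Control 1	10	control	1	44523335	72	972336	77	65	60	41	942568	1224561	3816369	0.119	0.008	0.009
Day 10 Control 2	10	control	2	31106461	73	972473	55	48	44	32	937025	1216470	3783515	0.115	0.008	0.009
Day 10 Control 3	10	control	3	31278928	71	976178	63	57	56	45	965823	1260295	4140910	0.117	0.011	0.013
Day 4 AZA 1	4	5AZA	1	35175861	78	974284	68	58	54	39	953024	1240912	3971269	0.121	0.005	0.007
Day 4 AZA 2	4	5AZA	2	25810214	80	979296	72	68	67	62	972892	1269534	4252504	0.119	0.017	0.018
Day 4 AZA 3	4	5AZA	3	51025989	81	973858	103	53	49	34	956954	1247256	3995715	0.124	0.009	0.011
Day 5 AZA 1	5	5AZA	1	23711109	77	974016	50	44	42	31	934472	1215456	3753189	0.122	0.009	0.011
Day 5 AZA 2	5	5AZA	2	38010117	80	976674	88	81	79	65	970660	1266406	4206109	0.119	0.010	0.012
Day 5 AZA 3	5	5AZA	3	24571651	78	972998	59	49	46	33	927143	1204554	3706979	0.129	0.009	0.010
Day 6 AZA 1	6	5AZA	1	32609015	78	973530	62	46	43	29	935134	1213880	3753222	0.121	0.005	0.007
Day 6 AZA 2	6	5AZA	2	36869188	78	974719	75	69	66	51	963066	1255704	4086914	0.119	0.009	0.010
Day 6 AZA 3	6	5AZA	3	26727193	80	974765	59	53	51	40	955764	1245567	3991086	0.122	0.011	0.014
Day 7 AZA 1	7	5AZA	1	37076497	78	972230	68	48	44	30	939065	1218808	3778410	0.120	0.007	0.008
Day 7 AZA 2	7	5AZA	2	27862914	81	973613	54	46	43	29	934476	1212377	3747479	0.118	0.005	0.006
Day 7 AZA 3	7	5AZA	3	32739443	80	973978	64	54	50	35	945266	1229569	3875733	0.120	0.005	0.007
Day 10 AZA 1	10	5AZA	1	32085678	77	974843	77	66	63	46	950340	1237985	3940037	0.124	0.009	0.011
Day 10 AZA 2	10	5AZA	2	31462613	79	973459	58	88	84	58	931975	1208968	3716882	0.121	0.006	0.007
Day 10 AZA 3	10	5AZA	3	25019781	80	972153	47	39	36	24	908946	1173978	3481932	0.119	0.005	0.006
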