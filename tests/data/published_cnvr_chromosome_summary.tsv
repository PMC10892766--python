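chrom	chrom_length	cnvr_count	cnvr_total_length	coverage_pct	max_size	mean_size	min_size
1	197778178	2761	4102658	2.1	642753	1485.9	51
2	149541958	2038	1795942	1.2	76049	881.2	51
3	110815227	1435	1011600	0.9	37549	704.9	51
4	91021375	1162	894849	1.0	104295	770.1	51
5	59471259	664	581860	1.0	38456	876.3	51
6	35339061	382	241170	0.7	21044	631.3	51
7	36318844	437	353483	1.0	36899	808.9	51
8	29613760	276	143465	0.5	20456	519.8	52
9	23556363	224	177489	0.8	15124	792.4	51
10	20214400	204	122553	0.6	12825	600.8	51
11	19755808	157	81894	0.4	16494	521.6	51
12	20438972	194	124811	0.6	19162	643.4	51
13	18437548	161	285249	1.5	50758	1771.7	51
14	15523295	135	89883	0.6	18875	665.8	51
15	12662000	71	80617	0.6	14389	1135.5	51
16	1595800	11	615070	38.5	542075	55915.5	63
17	10229956	57	22414	0.2	4896	393.2	51
18	11472971	78	101581	0.9	35771	1302.3	51
19	10411340	66	65454	0.6	12765	991.7	51
20	14040156	110	78193	0.6	16021	710.8	51
21	6776000	42	36126	0.5	27274	860.1	52
22	4690381	23	15414	0.3	4663	670.2	53
23	5830993	53	17315	0.3	6364	326.7	52
24	6352200	37	16508	0.3	6088	446.2	53
25	2575857	34	44705	1.7	10788	1314.9	52
26	5288600	30	23279	0.4	13044	776.0	51
27	5930361	56	425849	7.2	311709	7604.4	53
28	5407282	42	29718	0.5	12414	707.6	52
29	1064585	0	0	0	0	0	0
30	979082	21	8930	0.9	1139	425.2	54
31	2139823	13	308985	14.4	193165	23768.1	58
32	454000	0	0	0	0	0	0
33	3524363	19	1142884	32.4	504390	60151.8	52
34	2223258	30	28054	1.3	16716	935.1	73
35	327777	2	17147	5.2	15351	8573.5	1796
36	493600	7	7529	1.5	3094	1075.6	226
37	316000	0	0	0	0	0	0
38	298400	3	1258	0.4	477	419.3	365
overall	942910833	11035	13093936	1.4	642753	1186.6	51
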