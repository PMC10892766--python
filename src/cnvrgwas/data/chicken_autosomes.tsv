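chrom	length
1	197778178
2	149541958
3	110815227
4	91021375
5	59471259
6	35339061
7	36318844
8	29613760
9	23556363
10	20214400
11	19755808
12	20438972
13	18437548
14	15523295
15	12662000
16	1595800
17	10229956
18	11472971
19	10411340
20	14040156
21	6776000
22	4690381
23	5830993
24	6352200
25	2575857
26	5288600
27	5930361
28	5407282
29	1064585
30	979082
31	2139823
32	454000
33	3524363
34	2223258
35	327777
36	493600
37	316000
38	298400
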