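# hg38 chromosome-arm table built from standard chromosome lengths and
# centromere boundary positions. Coordinates are 1-based inclusive; for each
# chromosome, p end + 1 = q start. Acrocentric p-arms are flagged excluded
# from the arm-level aneuploidy score.
chrom	arm	start	end	excluded
1	p	1	123400000	0
1	q	123400001	248956422	0
2	p	1	93900000	0
2	q	93900001	242193529	0
3	p	1	90900000	0
3	q	90900001	198295559	0
4	p	1	50000000	0
4	q	50000001	190214555	0
5	p	1	48800000	0
5	q	48800001	181538259	0
6	p	1	59800000	0
6	q	59800001	170805979	0
7	p	1	60100000	0
7	q	60100001	159345973	0
8	p	1	45200000	0
8	q	45200001	145138636	0
9	p	1	43000000	0
9	q	43000001	138394717	0
10	p	1	39800000	0
10	q	39800001	133797422	0
11	p	1	53400000	0
11	q	53400001	135086622	0
12	p	1	35500000	0
12	q	35500001	133275309	0
13	p	1	17700000	1
13	q	17700001	114364328	0
14	p	1	17200000	1
14	q	17200001	107043718	0
15	p	1	19000000	1
15	q	19000001	101991189	0
16	p	1	36800000	0
16	q	36800001	90338345	0
17	p	1	25100000	0
17	q	25100001	83257441	0
18	p	1	18500000	0
18	q	18500001	80373285	0
19	p	1	26200000	0
19	q	26200001	58617616	0
20	p	1	28100000	0
20	q	28100001	64444167	0
21	p	1	12000000	1
21	q	12000001	46709983	0
22	p	1	15000000	1
22	q	15000001	50818468	0
X	p	1	60600000	0
X	q	60600001	156040895	0
Y	p	1	10400000	0
Y	q	10400001	57227415	0
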