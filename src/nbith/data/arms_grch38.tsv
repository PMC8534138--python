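chrom	arm	start	end
1	p	0	121700000
1	q	125100000	248956422
2	p	0	91800000
2	q	96000000	242193529
3	p	0	87800000
3	q	94000000	198295559
4	p	0	48200000
4	q	51800000	190214555
5	p	0	46100000
5	q	50000000	181538259
6	p	0	58500000
6	q	62600000	170805979
7	p	0	58100000
7	q	62100000	159345973
8	p	0	43200000
8	q	47200000	145138636
9	p	0	42200000
9	q	45500000	138394717
10	p	0	38000000
10	q	41600000	133797422
11	p	0	51000000
11	q	55800000	135086622
12	p	0	33200000
12	q	37800000	133275309
13	p	0	16500000
13	q	18900000	114364328
14	p	0	16100000
14	q	18200000	107043718
15	p	0	17500000
15	q	20500000	101991189
16	p	0	35300000
16	q	38400000	90338345
17	p	0	22700000
17	q	27400000	83257441
18	p	0	15400000
18	q	21500000	80373285
19	p	0	24200000
19	q	28100000	58617616
20	p	0	25700000
20	q	30400000	64444167
21	p	0	10900000
21	q	13000000	46709983
22	p	0	13700000
22	q	17400000	50818468
X	p	0	58100000
X	q	63800000	156040895
Y	p	0	10300000
Y	q	10600000	57227415
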