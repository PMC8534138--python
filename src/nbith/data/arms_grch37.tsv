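chrom	arm	start	end
1	p	0	121500000
1	q	125000000	249250621
2	p	0	90500000
2	q	96800000	243199373
3	p	0	87900000
3	q	93900000	198022430
4	p	0	48200000
4	q	52700000	191154276
5	p	0	46100000
5	q	50700000	180915260
6	p	0	58700000
6	q	63300000	171115067
7	p	0	58000000
7	q	61700000	159138663
8	p	0	43100000
8	q	48100000	146364022
9	p	0	47300000
9	q	50700000	141213431
10	p	0	38000000
10	q	42300000	135534747
11	p	0	51600000
11	q	55700000	135006516
12	p	0	33300000
12	q	38200000	133851895
13	p	0	16300000
13	q	19500000	115169878
14	p	0	16100000
14	q	19100000	107349540
15	p	0	15800000
15	q	20700000	102531392
16	p	0	34600000
16	q	38600000	90354753
17	p	0	22200000
17	q	25800000	81195210
18	p	0	15400000
18	q	19000000	78077248
19	p	0	24400000
19	q	28600000	59128983
20	p	0	25600000
20	q	29400000	63025520
21	p	0	10900000
21	q	14300000	48129895
22	p	0	12200000
22	q	17900000	51304566
X	p	0	58100000
X	q	63000000	155270560
Y	p	0	10100000
Y	q	13400000	59373566
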