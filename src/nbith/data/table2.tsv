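case_id	mycn_status	n_total_events	n_diff_events	pct_diff	efs_months	efs_event	os_months	os_event
1	non-MNA	8	5	62.50	92	No	92	No
2	non-MNA	9	2	22.22	37	Yes	60	Yes
3	non-MNA	10	4	40.00	23	Yes	46	Yes
4	non-MNA	10	1	10.00	16	Yes	48	Yes
5	non-MNA	10	1	10.00	129	No	129	No
6	non-MNA	11	3	27.27	27	Yes	55	No
7	non-MNA	11	8	72.73	98	No	98	No
8	non-MNA	12	5	41.67	20	Yes	23	Yes
9	non-MNA	15	1	6.67	17	Yes	57	Yes
10	non-MNA	14	1	7.14	12	Yes	25	Yes
11	non-MNA	20	4	20.00	61	No	61	No
12	non-MNA	21	4	19.05	22	Yes	22	Yes
13	non-MNA	21	7	33.33	22	Yes	32	Yes
14	non-MNA	23	14	60.87	104	No	104	No
33	MNA	4	4	100.00	127	No	127	No
34	MNA	4	2	50.00	71	No	71	No
35	MNA	5	2	40.00	31	Yes	31	Yes
36	MNA	5	2	40.00	42	No	42	No
37	MNA	5	1	20.00	7	Yes	10	Yes
38	MNA	5	1	20.00	11	Yes	11	Yes
39	MNA	7	4	57.14	48	No	48	No
40	MNA	11	2	18.18	65	No	65	No
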