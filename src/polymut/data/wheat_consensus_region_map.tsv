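group	arm	region	interval_start	interval_end	mapped_ests	observed_mutations
1	L	R1	0.00	0.32	86	0
1	L	R2	0.32	0.61	117	2
1	L	R3	0.61	1.00	203	14
1	S	R1	0.00	0.48	39	4
1	S	R2	0.48	0.70	30	9
1	S	R3	0.70	1.00	214	26
2	L	R1	0.00	0.36	50	5
2	L	R2	0.36	0.76	224	34
2	L	R3	0.76	1.00	229	77
2	S	R1	0.00	0.33	50	6
2	S	R2	0.33	0.75	98	27
2	S	R3	0.75	1.00	161	47
3	L	R1	0.00	0.27	106	11
3	L	R2	0.27	0.63	125	25
3	L	R3	0.63	1.00	328	91
3	S	R1	0.00	0.33	82	10
3	S	R2	0.33	0.78	156	38
3	S	R3	0.78	1.00	81	19
4	L	R1	0.00	0.31	42	14
4	L	R2	0.31	0.66	272	49
4	L	R3	0.66	1.00	360	78
4	S	R1	0.00	0.37	57	3
4	S	R2	0.37	0.67	52	10
4	S	R3	0.67	1.00	238	35
5	L	R1	0.00	0.35	31	2
5	L	R2	0.35	0.75	94	13
5	L	R3	0.75	1.00	395	70
5	S	R1	0.00	0.40	21	0
5	S	R2	0.40	0.71	75	10
5	S	R3	0.71	1.00	113	20
6	L	R1	0.00	0.36	55	8
6	L	R2	0.36	0.68	69	16
6	L	R3	0.68	1.00	159	20
6	S	R1	0.00	0.35	43	8
6	S	R2	0.35	0.76	70	8
6	S	R3	0.76	1.00	149	30
7	L	R1	0.00	0.33	77	19
7	L	R2	0.33	0.71	126	18
7	L	R3	0.71	1.00	212	32
7	S	R1	0.00	0.36	106	22
7	S	R2	0.36	0.61	93	14
7	S	R3	0.61	1.00	212	18
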