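	U	B	G	I	J	T	H	Wr	Av	W	Ap	Lo	L	R	Sti	Sta	Σ
U	0	0	120	6	0	3	6	52	0	242	2	0	6	2	0	41	480
B	1	0	9	0	0	0	0	0	0	4	0	0	0	0	0	60	74
G	15	59	0	0	7	24	8	8	73	315	19	0	7	9	8	469	1021
I	6	0	0	0	0	0	2	19	0	16	0	0	0	0	0	0	43
J	4	2	0	2	0	1	0	0	6	15	5	0	0	2	0	12	49
T	2	1	9	0	0	0	0	2	8	17	15	2	9	2	0	9	76
H	10	0	0	2	0	0	0	19	0	32	0	0	0	4	0	23	90
Wr	12	0	26	9	0	0	1	0	0	59	0	0	0	9	0	39	155
Av	52	10	20	2	7	12	0	3	0	169	38	15	6	27	7	78	446
W	247	5	375	2	11	13	13	2	25	0	488	1	4	18	7	243	1454
Ap	39	0	43	9	7	9	1	19	181	178	0	4	12	42	4	58	606
Lo	4	1	0	0	0	0	0	1	4	13	5	0	5	0	0	9	42
L	8	0	0	0	0	0	1	36	0	10	0	0	0	2	0	11	68
R	26	5	0	4	0	1	0	4	9	70	9	0	1	0	0	23	152
Sti	0	1	7	0	0	0	0	2	5	7	7	2	2	0	0	33	66
Sta	36	17	556	11	23	20	10	0	117	272	32	8	15	43	8	0	1168
Σ	462	101	1165	47	55	83	42	167	428	1419	620	32	67	160	34	1108	5990
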