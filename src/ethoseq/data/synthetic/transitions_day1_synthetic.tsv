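	U	B	G	I	J	T	H	Wr	Av	W	Ap	Lo	L	R	Sti	Sta	Σ
U	0	0	42	0	0	1	3	44	0	205	2	0	6	2	0	104	409
B	2	0	5	0	0	0	0	0	0	8	0	0	0	0	0	6	21
G	15	2	0	10	7	19	9	15	62	283	16	0	15	16	18	397	884
I	4	0	0	0	0	0	0	0	0	9	0	0	0	0	0	0	13
J	0	0	0	0	0	0	0	0	2	14	0	0	0	1	0	6	23
T	5	0	10	0	0	0	0	2	7	15	13	0	1	2	0	11	66
H	4	0	0	0	0	0	0	0	0	5	0	0	0	0	0	4	13
Wr	10	0	24	1	0	0	1	0	0	50	15	0	2	4	0	24	131
Av	44	0	17	2	3	10	0	3	0	143	32	13	5	23	3	79	377
W	209	4	277	15	11	15	14	25	20	0	413	19	15	18	15	234	1304
Ap	37	0	31	8	4	8	5	15	153	148	0	7	11	36	7	49	519
Lo	6	0	0	0	0	0	0	1	11	4	4	0	4	0	2	5	37
L	0	0	0	0	0	0	0	1	0	18	0	3	0	0	0	8	30
R	22	0	0	1	0	2	0	4	8	60	8	0	2	0	0	23	130
Sti	0	0	6	0	0	0	0	2	9	8	3	0	0	0	0	28	56
Sta	31	3	471	11	8	23	11	28	100	262	29	13	18	40	14	0	1062
Σ	389	9	883	48	33	78	43	140	372	1232	535	55	79	142	59	978	5075
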