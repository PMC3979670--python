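	U	B	G	I	J	T	H	Wr	Av	W	Ap	Lo	L	R	Sti	Sta	Σ
U	0	0	134	0	0	0	2	45	0	210	0	0	2	0	0	145	538
B	1	0	8	0	0	0	0	0	0	3	0	0	0	0	0	52	64
G	13	51	0	0	6	23	4	35	57	259	16	0	12	13	18	407	914
I	5	0	0	0	0	0	0	16	0	11	0	0	0	0	0	0	32
J	6	0	0	0	0	4	0	0	4	5	2	0	2	3	0	16	42
T	5	1	4	0	0	0	0	2	7	23	8	0	8	2	0	6	66
H	2	0	0	0	0	0	0	16	0	4	0	0	0	0	0	3	25
Wr	34	0	16	8	0	0	7	0	0	25	0	0	0	4	0	39	133
Av	45	0	37	2	4	7	0	14	0	101	48	13	5	23	6	71	376
W	214	4	272	4	9	8	9	2	22	0	424	1	3	18	6	171	1167
Ap	37	0	38	8	6	9	0	20	157	128	0	16	10	37	10	49	525
Lo	4	1	0	0	0	0	0	1	11	5	4	0	4	0	1	6	37
L	0	0	0	0	0	0	0	32	0	11	0	2	0	2	0	11	58
R	22	1	0	1	3	2	0	3	8	61	8	0	2	0	0	21	132
Sti	0	0	16	0	0	0	0	0	9	0	1	2	0	0	0	29	57
Sta	32	6	483	3	20	25	7	0	102	249	30	5	10	37	28	0	1037
Σ	420	64	1008	26	48	78	29	186	377	1095	541	39	58	139	69	1026	5203
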