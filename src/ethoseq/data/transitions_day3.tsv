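	U	B	G	I	J	T	H	Wr	Av	W	Ap	Lo	L	R	Sti	Sta	Σ
U	0	0	53	0	0	1	1	44	0	206	2	0	7	1	0	93	408
B	1	0	8	0	0	0	0	0	0	3	0	0	0	0	0	51	63
G	13	50	0	0	6	19	0	1	62	305	16	0	6	6	16	399	899
I	3	0	0	0	0	0	0	16	0	3	0	0	0	0	0	2	24
J	1	0	0	0	0	4	0	0	5	12	1	0	0	2	0	16	41
T	2	1	8	1	0	0	0	1	7	15	13	0	8	2	0	8	66
H	3	0	0	0	0	0	0	16	0	4	0	0	0	0	0	2	25
Wr	33	0	3	8	0	0	7	0	0	50	1	0	1	8	0	20	131
Av	44	0	17	1	3	10	0	2	0	144	32	13	7	23	3	79	378
W	210	3	322	2	9	8	0	2	22	0	415	1	3	18	5	233	1253
Ap	37	0	15	8	3	2	0	8	154	178	0	16	10	36	3	51	521
Lo	6	1	0	0	0	0	0	4	11	1	3	0	4	0	2	5	37
L	0	0	0	0	0	0	17	31	0	4	0	1	0	1	0	3	57
R	22	1	0	3	0	1	0	3	8	60	8	0	1	0	0	23	130
Sti	0	2	6	0	0	0	0	1	9	8	1	1	0	0	0	28	56
Sta	31	5	473	1	20	21	0	0	100	254	29	5	10	33	27	0	1009
Σ	406	63	905	24	41	66	25	129	378	1247	521	37	57	130	56	1013	5098
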