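	U	B	G	I	J	T	H	Wr	Av	W	Ap	Lo	L	R	Sti	Sta	Σ
U	0	0	58	0	0	1	2	62	0	291	3	0	7	3	0	147	574
B	0	0	23	0	0	0	0	0	0	0	0	0	0	0	0	72	95
G	18	71	0	0	8	30	9	56	85	364	23	1	8	18	23	564	1278
I	0	0	0	0	0	0	0	23	0	13	0	0	0	0	0	0	36
J	7	0	0	0	0	6	0	0	5	11	4	0	0	2	0	23	58
T	3	1	11	0	0	0	0	2	10	21	18	0	11	3	0	11	91
H	5	0	0	0	0	0	0	23	0	0	0	0	0	0	0	12	40
Wr	47	0	13	11	0	0	10	0	0	50	12	0	4	11	0	26	184
Av	62	0	52	4	6	14	0	20	0	147	52	18	7	33	7	112	534
W	297	13	381	13	13	14	15	12	31	0	587	16	12	25	12	303	1744
Ap	52	0	44	11	8	12	0	30	218	212	0	6	14	51	13	65	736
Lo	8	1	0	0	0	0	0	2	4	10	7	0	6	0	3	11	52
L	9	0	0	0	0	0	1	44	0	11	0	1	0	3	0	12	81
R	16	3	0	1	4	3	0	10	13	85	20	0	2	0	0	26	183
Sti	0	1	20	0	0	0	0	1	13	1	1	1	0	0	0	40	78
Sta	44	7	669	2	28	37	12	0	141	349	41	8	14	52	38	0	1442
Σ	568	97	1271	42	67	117	49	285	520	1565	768	51	85	201	96	1424	7206
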