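index	enzyme	kf	Km	Kmd	ec	genes
1	ManI	1923.75	827	0	3.2.1.113	MAN1A1, MAN1A2, MAN1B1, MAN1C1
2	ManI	100	5000	0	3.2.1.113	MAN1A1, MAN1A2, MAN1B1, MAN1C1
5	ManII	1923.75	200	0	3.2.1.114	MAN2A1, MAN2A2
6	ManII	1923.75	100	0	3.2.1.114	MAN2A1, MAN2A2
7	a6FucT	253	25	46	2.4.1.68	FUT8
8	GnTI	990	260	170	2.4.1.101	MGAT1
9	GnTII	1320	190	960	2.4.1.143	MGAT2
10	GnTIII	607.2	190	3100	2.4.1.144	MGAT3
11	GnTIV	187	3400	8300	2.4.1.145	MGAT4A, MGAT4B
12	GnTV	1410	130	3500	2.4.1.155	MGAT5
13	iGnT	24.66	700	55	2.4.1.149	B3GNT1, B3GNT2
14	b4GalT	8712	150	0	2.4.1.38	B4GALT1, B4GALT2, B4GALT3
15	a3SiaT	484.1	260	57	2.4.99.6	ST3GAL3
24	a3FucT	25	1400	9	2.4.1.152	FUT4, FUT7, FUT9
19	a3GalT	190	1150	12600	2.4.1.87	GGTA1
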