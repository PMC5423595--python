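index	enzyme	cosubstrate	coproduct	substrate	product	constraint
1	ManI	water	mannose	(Ma2Ma	(Ma	~*2Ma3(…Ma6)Ma6 & ~Ga3
2	ManI	water	mannose	(Ma3(Ma2Ma3(Ma6)Ma6)	(Ma3(Ma3(Ma6)Ma6)	~Ga3
5	ManII	water	mannose	(Ma3(Ma6)Ma6	(Ma6Ma6	(GNb2|Ma3 & ~Gnbis
6	ManII	water	mannose	(Ma6Ma6	(Ma6	(GNb2|Ma3 & ~Gnbis
7	a6FucT	GDP-Fuc	GDP	GNb4GN	GNb4(Fa6)GN	GNb2|Ma3 & #A = 0 & ~Gnbis
8	GnTI	UDP-GlcNAc	UDP	(Ma3(Ma3(Ma6)Ma6)Mb4	(GNb2Ma3(Ma3(Ma6)Ma6)Mb4
9	GnTII	UDP-GlcNAc	UDP	(GNb2|Ma3(Ma6)Mb4	(GNb2|Ma3(GNb2Ma6)Mb4
10	GnTIII	UDP-GlcNAc	UDP	GNb2|Ma3	GNb2|Ma3(GNb4)	~Ab & ~Gnbis & ~(Ma6Ma6)Mb4
11	GnTIV	UDP-GlcNAc	UDP	(GNb2Ma3	(GNb2(GNb4)Ma3	~Gnbis
12	GnTV	UDP-GlcNAc	UDP	(GNb2Ma6	(GNb2(GNb6)Ma6	~Gnbis
13	iGnT	UDP-GlcNAc	UDP	(Ab4GN	(GNb3Ab4GN
14	b4GalT	UDP-Gal	UDP	(GN	(Ab4GN	~*GNb4)(…Ma6)Mb4
15	a3SiaT	CMP-NeuAc	CMP	(Ab4GN	(NNa3Ab4GN
24	a3FucT	GDP-Fuc	GDP	(…Ab4GNb	(Fa3(…Ab4)GNb
19	a3GalT	UDP-Gal	UDP	(Ab4GN	(Aa3Ab4GN
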