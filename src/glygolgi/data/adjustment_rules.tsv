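rule_index	condition	kf_mult	km_mult	kmd_mult
1	#M = 9	1	6.552	1
1	#M = 8	1	4.024	1
1	#M = 7	1	1.696	1
1	Ma2Ma3(…Ma6)Ma6	1	8.620	1
10	~GNb2|Ma6	1	20.000	1
11	~GNb2|Ma6	1	5.000	1
11	Ab4GNb2|Ma6 or Ab4GNb6)Ma6	1	1.500	1
11	GNb6)Ma6	1	0.178	1
12	GNb4)Ma3	1	0.692	1
13	*_Ma3	1	10.000	1
13	*_GNb2Ma6	1	4.000	1
13	*_GNb2Ma3	1	4.000	1
14	*_GNb6)Ma6	1	0.800	1
14	*_GNb2|Ma6	1	5.400	1
14	*_GNb4)Ma3	1	0.667	1
14	Gnbis & GNb2|Ma6	1	3.620	1
14	~GNb2|Ma6	1	26.667	1
14	Ab4	1	0.343	1
15	#NN>1	1	5.000	1
24	(*Fa2Ab4	4.08	0.500	1
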