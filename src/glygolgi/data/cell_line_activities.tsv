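enzyme	Pro-5	Lec1	Lec2	Lec3.2.8.1	Lec4	LEC10	LEC11	LEC12	Lec13	LEC30
ManI	5.032	2.802	5.795	2.156	5.064	5.495	8.643	6.879	5.276	6.980
ManII	8.130	8.659	10.775	4.317	6.793	13.301	8.258	8.390	19.937	21.389
a6FucT	4.161	0.531	5.722	1.807	4.188	10.589	4.331	3.942	0.088	53.310
GnTI	1.049	0.098	1.499	0.173	1.228	1.428	1.325	1.333	1.159	1.907
GnTII	6.582	7.130	8.644	1.456	5.433	13.498	5.803	6.092	20.154	19.659
GnTIII	0.105	0.592	0.201	5.569	0.010	21.569	0.321	0.093	0.081	0.226
GnTIV	0.467	0.145	0.509	2.389	1.181	8.115	0.900	0.317	0.635	0.615
GnTV	2.183	1.530	4.048	8.633	0.409	13.158	3.142	1.784	4.391	4.626
iGnT	0.523	0.000	0.576	0.443	0.439	0.585	0.351	1.214	0.556	0.184
b4GalT	6.282	2.547	8.144	11.553	4.899	5.140	10.174	6.386	7.309	18.330
a3SiaT	0.081	0.179	0.004	0.290	0.047	0.034	0.231	0.068	0.054	0.031
a3FucT	0.006	0.000	0.001	0.248	0.003	0.005	0.078	0.764	0.009	0.567
a3GalT	0.028	0.095	0.007	1.126	0.017	0.011	0.095	0.107	0.032	0.057
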