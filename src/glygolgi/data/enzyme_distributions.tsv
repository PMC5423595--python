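enzyme	mean	alpha_plus_beta
ManI	0.346	6
ManII	0.479	6
a6FucT	0.479	6
GnTI	0.479	6
GnTII	0.479	6
GnTIII	0.618	6
GnTIV	0.479	6
GnTV	0.479	6
iGnT	0.479	6
b4GalT	0.812	6
a3SiaT	0.812	6
a3FucT	0.812	6
a3GalT	0.812	6
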