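parameter	c1	c2	c3	c4
residence_time_min	5.556	5.556	5.556	5.556
water	56000000	56000000	56000000	56000000
GDP-Fuc	5000	5000	5000	5000
UDP-GlcNAc	9143	9143	9143	9143
UDP-Gal	3810	3810	3810	3810
CMP-NeuAc	2286	2286	2286	2286
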