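name	expression
L-PHA	(Ab4…GNb2(Ab4…GNb6)Ma6
WGA	Count (NNa3Ab4GN
ConA	Ma3(…Ma3(…Ma6)Ma6)Mb4
Ricin	Count (Ab4GNb
Ricin(F)	Count (Ab4|GNb
LCA	-GNb2Ma3|(-GNb2(-GNb6)Ma6)Mb4GNb4(Fa6)GN or -GNb2Ma3|(-GNb2Ma6)Mb4GNb4(Fa6)GN
PSA	-GNb2Ma3|(-GNb2(-GNb6)Ma6)Mb4GNb4(Fa6)GN or -GNb2Ma3|(-GNb2Ma6)Mb4GNb4(Fa6)GN
E-PHA	GNb2|Ma3(GNb4)(-GNb2Ma6)M
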