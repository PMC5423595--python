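name	expression
High mannose	#GN = 2
Hybrid	#GN>2 & ~GNb2|Ma6
Monoantennary	GNb2Ma3|(Ma6)Mb4
Biantennary	GNb2Ma3|(…GNb2Ma6)Mb4
Triantennary1	GNb2(…GNb4)Ma3|(…GNb2Ma6)Mb4
Triantennary2	GNb2Ma3|(…GNb2(…GNb6)Ma6)Mb4
Tetraantennary	GNb2(…GNb4)Ma3|(…GNb2(…GNb6)Ma6)Mb4
Bisected	Ma3(GNb4)(…Ma6)Mb4
Lactosamine extensions	Count GNb3
Lactosamine groups	Count Ab4GN
Terminal alpha-galactose	Count (Aa
Terminal sialic acid	Count (NN
Core Fucose	GNb4(Fa6)GN
Branch fucose	Count Fa3
Lex	Count (Fa3(Ab4)GN
SLex	Count (Fa3(NNa3Ab4)GN
VIM-2	Count (Fa3(NNa3Ab4GNb3Ab4)GN
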