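acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
aldehyde	[CX3H1](=O)[#6]
alkyl_halide_activated	[CH2X4][Br,I]
epoxide	C1OC1
aziridine	C1NC1
isocyanate	N=C=O
isothiocyanate	N=C=S
michael_acceptor_nitrile	C=C-C#N
michael_acceptor_carbonyl	[CX3]=[CX3][CX3](=[OX1])[!N]
anhydride	[CX3](=[OX1])O[CX3](=[OX1])
sulfonyl_halide	S(=O)(=O)[F,Cl,Br,I]
azo	[#6]N=N[#6]
diazo	[N+]=[N-]
peroxide	[OX2][OX2]
thiol	[#6][SX2H]
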