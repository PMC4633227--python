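FunctionalGroup	SMARTS
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
aldehyde	[CX3H1](=O)[#6]
epoxide	C1OC1
aziridine	C1NC1
azide	[NX2]=[NX2+]=[NX1-]
diazonium	[NX2+]#[NX1]
azo	[#6][NX2]=[NX2][#6]
hydrazine	[NX3;!$(NC=O)][NX3;!$(NC=O)]
nitroso	[#6][NX2]=[OX1]
alkyl_halide_reactive	[CX4;!$(C(F)(F)F)][Br,I]
michael_acceptor_ketone	[CX3]=[CX3][CX3]=[OX1]
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
thiol	[SX2H]
disulfide	[SX2][SX2]
peroxide	[OX2][OX2]
oxime	[CX3]=[NX2][OX2H]
quaternary_ammonium	[NX4+]
crown_polyether	[OX2H0][CX4][CX4][OX2H0][CX4][CX4][OX2H0]
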