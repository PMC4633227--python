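FunctionalGroup	SMARTS
alcohol	[OX2H][CX4]
phenol	[OX2H][c]
carboxylic_acid	[CX3](=O)[OX2H1]
carboxylate	[CX3](=O)[O-]
ester	[#6][CX3](=O)[OX2H0][#6]
lactone	[CX3](=O)[OX2H0][#6;R]
ether	[CX4][OX2H0][CX4]
aromatic_ether	[c][OX2H0][#6]
aldehyde	[CX3H1](=O)[#6]
ketone	[#6][CX3](=[OX1])[#6]
carbonyl	[CX3]=[OX1]
primary_amine	[NX3;H2;!$(NC=O)][CX4]
secondary_amine	[NX3;H1;!$(NC=O)]([CX4])[CX4]
tertiary_amine	[NX3;H0;!$(NC=O);!$(N=O)]([CX4])([CX4])[CX4]
aromatic_amine	[NX3;!$(NC=O)][c]
amide	[NX3][CX3](=[OX1])
nitro	[$([NX3](=O)=O),$([NX3+](=O)[O-])]
nitrile	[NX1]#[CX2]
imine	[CX3]=[NX2]
azo	[#6][NX2]=[NX2][#6]
hydrazine	[NX3][NX3]
hydroxylamine	[NX3][OX2H]
oxime	[CX3]=[NX2][OX2H]
guanidine	[NX3][CX3](=[NX2])[NX3]
urea	[NX3][CX3](=[OX1])[NX3]
carbamate	[NX3][CX3](=[OX1])[OX2][#6]
isocyanate	[NX2]=[CX2]=[OX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
thiol	[SX2H]
thioether	[#6][SX2H0][#6]
disulfide	[SX2][SX2]
thione	[CX3]=[SX1]
sulfoxide	[#16X3]=[OX1]
sulfone	[#16X4](=[OX1])=[OX1]
sulfonamide	[#16X4](=[OX1])(=[OX1])[NX3]
sulfonic_acid	[#16X4](=[OX1])(=[OX1])[OX2H]
phosphate	[PX4](=[OX1])([OX2])([OX2])[OX2]
phosphonate	[PX4](=[OX1])([OX2])[#6]
fluoro	[F]
chloro	[Cl]
bromo	[Br]
iodo	[I]
trifluoromethyl	[CX4]([F])([F])[F]
alkene	[CX3]=[CX3]
alkyne	[CX2]#[CX2]
allene	[CX3]=[CX2]=[CX3]
benzene_ring	c1ccccc1
aromatic_nitrogen	[nX2,nX3]
aromatic_oxygen	[oX2]
aromatic_sulfur	[sX2]
pyridine	n1ccccc1
furan	o1cccc1
thiophene	s1cccc1
imidazole	c1cnc[nH]1
epoxide	C1OC1
aziridine	C1NC1
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
anhydride	[CX3](=[OX1])[OX2][CX3](=[OX1])
hydroxamic_acid	[CX3](=[OX1])[NX3][OX2H]
enol	[OX2H][CX3]=[CX3]
hemiacetal	[OX2H][CX4][OX2H0]
vinyl_ether	[OX2H0][CX3]=[CX3]
quaternary_ammonium	[NX4+]
n_oxide	[NX3+][O-]
azide	[NX2]=[NX2+]=[NX1-]
diazonium	[NX2+]#[NX1]
boronic_acid	[BX3]([OX2H])[OX2H]
platinum	[Pt]
gold	[Au]
iron	[Fe]
copper	[Cu]
zinc	[Zn]
ruthenium	[Ru]
arsenic	[As]
titanium	[Ti]
gadolinium	[Gd]
selenium	[Se]
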