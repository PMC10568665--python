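# Curated functional-group SMARTS used as the base of the substructure
# (FP4-style) key set and by the synthetic-data toxicophore library.
# Format: name<TAB>SMARTS. Lines starting with '#' are ignored.
alcohol	[OX2H][CX4]
phenol	[OX2H]c
carboxylic_acid	C(=O)[OX2H1]
carboxylate	C(=O)[O-]
ester	[#6]C(=O)O[#6]
lactone	[C;R](=O)[O;R]
ether	[OD2]([#6])[#6]
aromatic_ether	c[OX2][CX4]
diaryl_ether	c[OX2]c
methoxy	[OX2][CH3]
aldehyde	[CX3H1]=O
aromatic_aldehyde	c[CX3H1]=O
ketone	[#6][CX3](=O)[#6]
aryl_ketone	c[CX3](=O)
quinone	O=C1C=CC(=O)C=C1
amide	C(=O)[NX3]
lactam	[C;R](=O)[N;R]
primary_amine	[NX3;H2][CX4]
secondary_amine	[NX3;H1]([CX4])[CX4]
tertiary_amine	[NX3]([CX4])([CX4])[CX4]
aromatic_amine	c[NX3;H2]
n_methylamino	[NX3][CH3]
quaternary_ammonium	[NX4+]
nitro	[N+](=O)[O-]
aromatic_nitro	c[N+](=O)[O-]
aliphatic_nitro	[CX4][N+](=O)[O-]
nitroso	[#6][NX2]=O
nitrosamine	[NX3][NX2]=O
nitrate_ester	[OX2][N+](=O)[O-]
azo	[#6]N=N[#6]
azide	N=[N+]=[N-]
hydrazine	[NX3][NX3]
hydrazone	[CX3]=N[NX3]
oxime	[CX3]=N[OX2H]
hydroxylamine	[NX3][OX2H]
imine	[CX3]=[NX2]
nitrile	C#N
isocyanate	N=C=O
isothiocyanate	N=C=S
cyanamide	[NX3]C#N
urea	NC(=O)N
thiourea	NC(=S)N
carbamate	NC(=O)O
guanidine	NC(=N)N
thiol	[SX2H]
thioether	[SX2]([#6])[#6]
disulfide	[SX2][SX2]
thioamide	C(=S)[NX3]
thione	[#6]=[SX1]
sulfoxide	[#16X3]=[OX1]
sulfone	S(=O)(=O)
sulfonamide	S(=O)(=O)[NX3]
sulfonic_acid	S(=O)(=O)[OX2H]
sulfate_ester	OS(=O)(=O)O
phosphate	P(=O)(O)O
phosphonate	P(=O)([#6])O
alkyl_fluoride	[CX4]F
alkyl_chloride	[CX4]Cl
alkyl_bromide	[CX4]Br
alkyl_iodide	[CX4]I
aryl_fluoride	cF
aryl_chloride	cCl
aryl_bromide	cBr
aryl_iodide	cI
acyl_halide	C(=O)[F,Cl,Br,I]
trifluoromethyl	C(F)(F)F
trichloromethyl	C(Cl)(Cl)Cl
vinyl_halide	C=C[F,Cl,Br,I]
allyl_halide	C=CC[F,Cl,Br,I]
alpha_halo_ketone	[CX3](=O)[CX4][F,Cl,Br,I]
epoxide	C1OC1
aziridine	C1NC1
oxetane	C1COC1
peroxide	[OX2][OX2]
anhydride	C(=O)OC(=O)
carbonate	OC(=O)O
alkene	C=C
alkyne	C#C
diene	C=CC=C
michael_acceptor	C=C[CX3]=O
enol	C=C[OX2H]
vinyl_ether	C=C[OX2][#6]
benzene_ring	c1ccccc1
toluene_like	Cc1ccccc1
styrene_like	C=Cc1ccccc1
biphenyl	c1ccccc1-c1ccccc1
naphthalene	c1ccc2ccccc2c1
pyridine	c1ccncc1
pyrrole	c1cc[nH]c1
furan	c1ccoc1
thiophene	c1ccsc1
imidazole	c1cnc[nH]1
pyrimidine	c1cncnc1
tert_butyl	[CX4]([CH3])([CH3])[CH3]
isopropyl	[CH1]([CH3])[CH3]
methylenedioxy	[OX2][CH2][OX2]
n_oxide	[#7+][O-]
acetal	[CX4]([OX2])[OX2]
halogenated_amine	[NX3][F,Cl,Br,I]
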