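# Curated subset of the Glaxo Wellcome structural alert set (name, SMARTS,
# source). A small bundled selection for desk-scale evaluation, not the full
# published catalog; users can supply a complete catalog as a TSV.
reactive_alkyl_halide	[Br,Cl,I][CX4]	Glaxo
acyl_halide	[CX3](=O)[F,Cl,Br,I]	Glaxo
aldehyde	[CX3H1](=O)[#6]	Glaxo
epoxide	C1OC1	Glaxo
aziridine	C1NC1	Glaxo
thiol	[SX2H]	Glaxo
disulfide	[SX2][SX2]	Glaxo
peroxide	[OX2][OX2]	Glaxo
isocyanate	N=C=O	Glaxo
hydrazine	[NX3][NX3]	Glaxo
carbodiimide	N=C=N	Glaxo
beta_lactam	O=C1CCN1	Glaxo
phosphorus_halide	P[F,Cl,Br,I]	Glaxo
nitroso	[#6][NX2]=O	Glaxo
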