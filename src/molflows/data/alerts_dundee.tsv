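# Curated subset of the Dundee structural alert set (name, SMARTS, source).
# This is a small bundled selection for desk-scale evaluation, not the full
# published catalog; users can supply a complete catalog as a TSV.
nitro_group	[N+](=O)[O-]	Dundee
michael_acceptor	C=CC=O	Dundee
sulfonate_ester	COS(=O)=O	Dundee
quinone	O=C1C=CC(=O)C=C1	Dundee
hydroxylamine	[NX3][OX2H]	Dundee
thiourea	NC(=S)N	Dundee
isothiocyanate	N=C=S	Dundee
acid_anhydride	C(=O)OC(=O)	Dundee
acyl_hydrazide	C(=O)N[NX3]	Dundee
polyene	C=CC=CC=C	Dundee
alpha_halo_ketone	[F,Cl,Br,I][CX4][CX3]=O	Dundee
diazonium	[N+]#N	Dundee
sulfonyl_halide	S(=O)(=O)[F,Cl,Br,I]	Dundee
imine	[CX3]=[NX2][#6]	Dundee
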