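# allowed valencies per (element, formal charge); valency = sum of bond orders
# with aromatic bonds counting 1.5. Carbon additionally allows 4.5 so that
# aromatic-fusion bridgeheads (three aromatic bonds) count as stable.
# element	charge	allowed valencies
H	0	1
B	0	3
C	0	4,4.5
C	-1	3
C	1	3
N	0	3
N	-1	2
N	1	4
O	0	2
O	-1	1
O	1	3
F	0	1
Si	0	4
P	0	3,5
P	1	4
S	0	2,4,6
S	-1	1
S	1	3,5
Cl	0	1
Br	0	1
I	0	1
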