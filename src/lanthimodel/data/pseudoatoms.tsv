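# pseudoatom expansion map: residue_code	pseudoatom	member_atoms (comma)
# methyl pseudoatoms map to the methyl carbon of the reduced atom set;
# QA on glycine maps to the two alpha protons
ALA	MB	CB
ALA	QB	CB
DAL	MB	CB
DAL	QB	CB
DHB	MG	CG
ABU	MG	CG
DBB	MG	CG
THR	MG	CG
DTH	MG	CG
GLY	QA	HA2,HA3
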