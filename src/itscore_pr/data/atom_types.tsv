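# (molecule kind, residue, atom name) -> atom type symbol
# '*' matches any standard residue; RNA primed names also accept the '*' dialect (C4* == C4')
kind	residue	atom	symbol
protein	ARG	CZ	C2+
protein	ASP	CG	C2-
protein	GLU	CD	C2-
protein	*	C	C2M
protein	ASN	CG	C2S
protein	GLN	CD	C2S
protein	HIS	CD2	Car
protein	HIS	CE1	Car
protein	HIS	CG	Car
protein	PHE	CD1	Car
protein	PHE	CD2	Car
protein	PHE	CE1	Car
protein	PHE	CE2	Car
protein	PHE	CG	Car
protein	PHE	CZ	Car
protein	TRP	CD1	Car
protein	TRP	CD2	Car
protein	TRP	CE2	Car
protein	TRP	CE3	Car
protein	TRP	CG	Car
protein	TRP	CH2	Car
protein	TRP	CZ2	Car
protein	TRP	CZ3	Car
protein	TYR	CD1	Car
protein	TYR	CD2	Car
protein	TYR	CE1	Car
protein	TYR	CE2	Car
protein	TYR	CG	Car
protein	TYR	CZ	Car
protein	ALA	CB	C3C
protein	ARG	CB	C3C
protein	ARG	CG	C3C
protein	ASN	CB	C3C
protein	ASP	CB	C3C
protein	GLN	CB	C3C
protein	GLN	CG	C3C
protein	GLU	CB	C3C
protein	GLU	CG	C3C
protein	HIS	CB	C3C
protein	ILE	CB	C3C
protein	ILE	CD1	C3C
protein	ILE	CG1	C3C
protein	ILE	CG2	C3C
protein	LEU	CB	C3C
protein	LEU	CD1	C3C
protein	LEU	CD2	C3C
protein	LEU	CG	C3C
protein	LYS	CB	C3C
protein	LYS	CD	C3C
protein	LYS	CG	C3C
protein	MET	CB	C3C
protein	PHE	CB	C3C
protein	PRO	CB	C3C
protein	PRO	CG	C3C
protein	THR	CG2	C3C
protein	TRP	CB	C3C
protein	TYR	CB	C3C
protein	VAL	CB	C3C
protein	VAL	CG1	C3C
protein	VAL	CG2	C3C
protein	*	CA	C3A
protein	ARG	CD	C3X
protein	CYS	CB	C3X
protein	LYS	CE	C3X
protein	MET	CE	C3X
protein	MET	CG	C3X
protein	PRO	CD	C3X
protein	SER	CB	C3X
protein	THR	CB	C3X
protein	ALA	N	N2N
protein	ARG	N	N2N
protein	ASN	N	N2N
protein	ASP	N	N2N
protein	CYS	N	N2N
protein	GLN	N	N2N
protein	GLU	N	N2N
protein	GLY	N	N2N
protein	HIS	N	N2N
protein	ILE	N	N2N
protein	LEU	N	N2N
protein	LYS	N	N2N
protein	MET	N	N2N
protein	PHE	N	N2N
protein	PRO	N	N2N
protein	SER	N	N2N
protein	THR	N	N2N
protein	TRP	N	N2N
protein	TYR	N	N2N
protein	VAL	N	N2N
protein	ARG	NH1	N2+
protein	ARG	NH2	N2+
protein	ASN	ND2	N2X
protein	GLN	NE2	N2X
protein	HIS	ND1	Nar
protein	HIS	NE2	Nar
protein	TRP	NE1	Nar
protein	ARG	NE	N21
protein	LYS	NZ	N3+
protein	*	O	O2M
protein	ASN	OD1	O2S
protein	GLN	OE1	O2S
protein	SER	OG	O3H
protein	THR	OG1	O3H
protein	TYR	OH	O3H
protein	ASP	OD1	O2-
protein	ASP	OD2	O2-
protein	GLU	OE1	O2-
protein	GLU	OE2	O2-
protein	CYS	SG	S31
protein	MET	SD	S30
protein	*	OXT	O2-
rna	C	C2	C2X
rna	G	C6	C2X
rna	U	C2	C2X
rna	U	C4	C2X
rna	C	C4	Car
rna	C	C5	Car
rna	C	C6	Car
rna	G	C2	Car
rna	U	C5	Car
rna	U	C6	Car
rna	A	C2	Car
rna	A	C4	Car
rna	A	C5	Car
rna	A	C6	Car
rna	A	C8	Car
rna	G	C4	Car
rna	G	C5	Car
rna	G	C8	Car
rna	A	C1'	C3X
rna	A	C2'	C3X
rna	A	C3'	C3X
rna	A	C4'	C3X
rna	A	C5'	C3X
rna	C	C1'	C3X
rna	C	C2'	C3X
rna	C	C3'	C3X
rna	C	C4'	C3X
rna	C	C5'	C3X
rna	G	C1'	C3X
rna	G	C2'	C3X
rna	G	C3'	C3X
rna	G	C4'	C3X
rna	G	C5'	C3X
rna	U	C1'	C3X
rna	U	C2'	C3X
rna	U	C3'	C3X
rna	U	C4'	C3X
rna	U	C5'	C3X
rna	C	N1	N2N
rna	G	N1	N2N
rna	U	N1	N2N
rna	U	N3	N2N
rna	A	N6	N2X
rna	C	N4	N2X
rna	G	N2	N2X
rna	C	N3	Nar
rna	G	N3	Nar
rna	A	N1	Nar
rna	A	N3	Nar
rna	A	N7	Nar
rna	G	N7	Nar
rna	A	N9	N21
rna	G	N9	N21
rna	C	O2	O2
rna	G	O6	O2
rna	U	O2	O2
rna	U	O4	O2
rna	A	O2'	O31
rna	C	O2'	O31
rna	G	O2'	O31
rna	U	O2'	O31
rna	A	O3'	O32
rna	A	O4'	O32
rna	A	O5'	O32
rna	C	O3'	O32
rna	C	O4'	O32
rna	C	O5'	O32
rna	G	O3'	O32
rna	G	O4'	O32
rna	G	O5'	O32
rna	U	O3'	O32
rna	U	O4'	O32
rna	U	O5'	O32
rna	A	OP1	O2-
rna	A	OP2	O2-
rna	C	OP1	O2-
rna	C	OP2	O2-
rna	G	OP1	O2-
rna	G	OP2	O2-
rna	U	OP1	O2-
rna	U	OP2	O2-
rna	A	P	P
rna	C	P	P
rna	G	P	P
rna	U	P	P
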