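residue	atom	moiety
ALA	CB	sc1
ARG	CB	sc1
ARG	CG	sc1
ARG	CD	sc1
ARG	NE	sc2
ARG	CZ	sc2
ARG	NH1	sc2
ARG	NH2	sc2
ASN	CB	sc1
ASN	CG	sc2
ASN	OD1	sc2
ASN	ND2	sc2
ASP	CB	sc1
ASP	CG	sc2
ASP	OD1	sc2
ASP	OD2	sc2
CYS	CB	sc1
CYS	SG	sc1
GLN	CB	sc1
GLN	CG	sc1
GLN	CD	sc2
GLN	OE1	sc2
GLN	NE2	sc2
GLU	CB	sc1
GLU	CG	sc1
GLU	CD	sc2
GLU	OE1	sc2
GLU	OE2	sc2
HIS	CB	sc1
HIS	CG	sc2
HIS	ND1	sc2
HIS	CD2	sc2
HIS	CE1	sc2
HIS	NE2	sc2
ILE	CB	sc1
ILE	CG1	sc1
ILE	CG2	sc1
ILE	CD1	sc1
LEU	CB	sc1
LEU	CG	sc1
LEU	CD1	sc1
LEU	CD2	sc1
LYS	CB	sc1
LYS	CG	sc1
LYS	CD	sc1
LYS	CE	sc2
LYS	NZ	sc2
MET	CB	sc1
MET	CG	sc1
MET	SD	sc1
MET	CE	sc1
PHE	CB	sc1
PHE	CG	sc2
PHE	CD1	sc2
PHE	CD2	sc2
PHE	CE1	sc2
PHE	CE2	sc2
PHE	CZ	sc2
PRO	CB	sc1
PRO	CG	sc1
PRO	CD	sc1
SER	CB	sc1
SER	OG	sc1
THR	CB	sc1
THR	OG1	sc1
THR	CG2	sc1
TRP	CB	sc1
TRP	CG	sc2
TRP	CD1	sc2
TRP	CD2	sc2
TRP	NE1	sc2
TRP	CE2	sc2
TRP	CE3	sc2
TRP	CZ2	sc2
TRP	CZ3	sc2
TRP	CH2	sc2
TYR	CB	sc1
TYR	CG	sc2
TYR	CD1	sc2
TYR	CD2	sc2
TYR	CE1	sc2
TYR	CE2	sc2
TYR	CZ	sc2
TYR	OH	sc2
VAL	CB	sc1
VAL	CG1	sc1
VAL	CG2	sc1
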