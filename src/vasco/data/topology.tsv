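# residue topology: standard amino-acid connectivity, version 1
residue	atom	element	n_h	aromatic	parent
ALA	N	N	1	0	-
ALA	CA	C	1	0	-
ALA	C	C	0	0	-
ALA	O	O	0	0	-
ALA	CB	C	3	0	-
ALA	H	H	0	0	N
ALA	HA	H	0	0	CA
ALA	HB1	H	0	0	CB
ALA	HB2	H	0	0	CB
ALA	HB3	H	0	0	CB
ARG	N	N	1	0	-
ARG	CA	C	1	0	-
ARG	C	C	0	0	-
ARG	O	O	0	0	-
ARG	CB	C	2	0	-
ARG	CG	C	2	0	-
ARG	CD	C	2	0	-
ARG	NE	N	1	0	-
ARG	CZ	C	0	0	-
ARG	NH1	N	2	0	-
ARG	NH2	N	2	0	-
ARG	H	H	0	0	N
ARG	HA	H	0	0	CA
ARG	HB2	H	0	0	CB
ARG	HB3	H	0	0	CB
ARG	HG2	H	0	0	CG
ARG	HG3	H	0	0	CG
ARG	HD2	H	0	0	CD
ARG	HD3	H	0	0	CD
ARG	HE	H	0	0	NE
ARG	HH11	H	0	0	NH1
ARG	HH12	H	0	0	NH1
ARG	HH21	H	0	0	NH2
ARG	HH22	H	0	0	NH2
ASN	N	N	1	0	-
ASN	CA	C	1	0	-
ASN	C	C	0	0	-
ASN	O	O	0	0	-
ASN	CB	C	2	0	-
ASN	CG	C	0	0	-
ASN	OD1	O	0	0	-
ASN	ND2	N	2	0	-
ASN	H	H	0	0	N
ASN	HA	H	0	0	CA
ASN	HB2	H	0	0	CB
ASN	HB3	H	0	0	CB
ASN	HD21	H	0	0	ND2
ASN	HD22	H	0	0	ND2
ASP	N	N	1	0	-
ASP	CA	C	1	0	-
ASP	C	C	0	0	-
ASP	O	O	0	0	-
ASP	CB	C	2	0	-
ASP	CG	C	0	0	-
ASP	OD1	O	0	0	-
ASP	OD2	O	0	0	-
ASP	H	H	0	0	N
ASP	HA	H	0	0	CA
ASP	HB2	H	0	0	CB
ASP	HB3	H	0	0	CB
CYS	N	N	1	0	-
CYS	CA	C	1	0	-
CYS	C	C	0	0	-
CYS	O	O	0	0	-
CYS	CB	C	2	0	-
CYS	SG	S	1	0	-
CYS	H	H	0	0	N
CYS	HA	H	0	0	CA
CYS	HB2	H	0	0	CB
CYS	HB3	H	0	0	CB
CYS	HG	H	0	0	SG
GLN	N	N	1	0	-
GLN	CA	C	1	0	-
GLN	C	C	0	0	-
GLN	O	O	0	0	-
GLN	CB	C	2	0	-
GLN	CG	C	2	0	-
GLN	CD	C	0	0	-
GLN	OE1	O	0	0	-
GLN	NE2	N	2	0	-
GLN	H	H	0	0	N
GLN	HA	H	0	0	CA
GLN	HB2	H	0	0	CB
GLN	HB3	H	0	0	CB
GLN	HG2	H	0	0	CG
GLN	HG3	H	0	0	CG
GLN	HE21	H	0	0	NE2
GLN	HE22	H	0	0	NE2
GLU	N	N	1	0	-
GLU	CA	C	1	0	-
GLU	C	C	0	0	-
GLU	O	O	0	0	-
GLU	CB	C	2	0	-
GLU	CG	C	2	0	-
GLU	CD	C	0	0	-
GLU	OE1	O	0	0	-
GLU	OE2	O	0	0	-
GLU	H	H	0	0	N
GLU	HA	H	0	0	CA
GLU	HB2	H	0	0	CB
GLU	HB3	H	0	0	CB
GLU	HG2	H	0	0	CG
GLU	HG3	H	0	0	CG
GLY	N	N	1	0	-
GLY	CA	C	2	0	-
GLY	C	C	0	0	-
GLY	O	O	0	0	-
GLY	H	H	0	0	N
GLY	HA2	H	0	0	CA
GLY	HA3	H	0	0	CA
HIS	N	N	1	0	-
HIS	CA	C	1	0	-
HIS	C	C	0	0	-
HIS	O	O	0	0	-
HIS	CB	C	2	0	-
HIS	CG	C	0	1	-
HIS	ND1	N	1	1	-
HIS	CD2	C	1	1	-
HIS	CE1	C	1	1	-
HIS	NE2	N	1	1	-
HIS	H	H	0	0	N
HIS	HA	H	0	0	CA
HIS	HB2	H	0	0	CB
HIS	HB3	H	0	0	CB
HIS	HD1	H	0	0	ND1
HIS	HD2	H	0	0	CD2
HIS	HE1	H	0	0	CE1
HIS	HE2	H	0	0	NE2
ILE	N	N	1	0	-
ILE	CA	C	1	0	-
ILE	C	C	0	0	-
ILE	O	O	0	0	-
ILE	CB	C	1	0	-
ILE	CG1	C	2	0	-
ILE	CG2	C	3	0	-
ILE	CD1	C	3	0	-
ILE	H	H	0	0	N
ILE	HA	H	0	0	CA
ILE	HB	H	0	0	CB
ILE	HG12	H	0	0	CG1
ILE	HG13	H	0	0	CG1
ILE	HG21	H	0	0	CG2
ILE	HG22	H	0	0	CG2
ILE	HG23	H	0	0	CG2
ILE	HD11	H	0	0	CD1
ILE	HD12	H	0	0	CD1
ILE	HD13	H	0	0	CD1
LEU	N	N	1	0	-
LEU	CA	C	1	0	-
LEU	C	C	0	0	-
LEU	O	O	0	0	-
LEU	CB	C	2	0	-
LEU	CG	C	1	0	-
LEU	CD1	C	3	0	-
LEU	CD2	C	3	0	-
LEU	H	H	0	0	N
LEU	HA	H	0	0	CA
LEU	HB2	H	0	0	CB
LEU	HB3	H	0	0	CB
LEU	HG	H	0	0	CG
LEU	HD11	H	0	0	CD1
LEU	HD12	H	0	0	CD1
LEU	HD13	H	0	0	CD1
LEU	HD21	H	0	0	CD2
LEU	HD22	H	0	0	CD2
LEU	HD23	H	0	0	CD2
LYS	N	N	1	0	-
LYS	CA	C	1	0	-
LYS	C	C	0	0	-
LYS	O	O	0	0	-
LYS	CB	C	2	0	-
LYS	CG	C	2	0	-
LYS	CD	C	2	0	-
LYS	CE	C	2	0	-
LYS	NZ	N	3	0	-
LYS	H	H	0	0	N
LYS	HA	H	0	0	CA
LYS	HB2	H	0	0	CB
LYS	HB3	H	0	0	CB
LYS	HG2	H	0	0	CG
LYS	HG3	H	0	0	CG
LYS	HD2	H	0	0	CD
LYS	HD3	H	0	0	CD
LYS	HE2	H	0	0	CE
LYS	HE3	H	0	0	CE
LYS	HZ1	H	0	0	NZ
LYS	HZ2	H	0	0	NZ
LYS	HZ3	H	0	0	NZ
MET	N	N	1	0	-
MET	CA	C	1	0	-
MET	C	C	0	0	-
MET	O	O	0	0	-
MET	CB	C	2	0	-
MET	CG	C	2	0	-
MET	SD	S	0	0	-
MET	CE	C	3	0	-
MET	H	H	0	0	N
MET	HA	H	0	0	CA
MET	HB2	H	0	0	CB
MET	HB3	H	0	0	CB
MET	HG2	H	0	0	CG
MET	HG3	H	0	0	CG
MET	HE1	H	0	0	CE
MET	HE2	H	0	0	CE
MET	HE3	H	0	0	CE
PHE	N	N	1	0	-
PHE	CA	C	1	0	-
PHE	C	C	0	0	-
PHE	O	O	0	0	-
PHE	CB	C	2	0	-
PHE	CG	C	0	1	-
PHE	CD1	C	1	1	-
PHE	CD2	C	1	1	-
PHE	CE1	C	1	1	-
PHE	CE2	C	1	1	-
PHE	CZ	C	1	1	-
PHE	H	H	0	0	N
PHE	HA	H	0	0	CA
PHE	HB2	H	0	0	CB
PHE	HB3	H	0	0	CB
PHE	HD1	H	0	0	CD1
PHE	HD2	H	0	0	CD2
PHE	HE1	H	0	0	CE1
PHE	HE2	H	0	0	CE2
PHE	HZ	H	0	0	CZ
PRO	N	N	0	0	-
PRO	CA	C	1	0	-
PRO	C	C	0	0	-
PRO	O	O	0	0	-
PRO	CB	C	2	0	-
PRO	CG	C	2	0	-
PRO	CD	C	2	0	-
PRO	HA	H	0	0	CA
PRO	HB2	H	0	0	CB
PRO	HB3	H	0	0	CB
PRO	HG2	H	0	0	CG
PRO	HG3	H	0	0	CG
PRO	HD2	H	0	0	CD
PRO	HD3	H	0	0	CD
SER	N	N	1	0	-
SER	CA	C	1	0	-
SER	C	C	0	0	-
SER	O	O	0	0	-
SER	CB	C	2	0	-
SER	OG	O	1	0	-
SER	H	H	0	0	N
SER	HA	H	0	0	CA
SER	HB2	H	0	0	CB
SER	HB3	H	0	0	CB
SER	HG	H	0	0	OG
THR	N	N	1	0	-
THR	CA	C	1	0	-
THR	C	C	0	0	-
THR	O	O	0	0	-
THR	CB	C	1	0	-
THR	OG1	O	1	0	-
THR	CG2	C	3	0	-
THR	H	H	0	0	N
THR	HA	H	0	0	CA
THR	HB	H	0	0	CB
THR	HG1	H	0	0	OG1
THR	HG21	H	0	0	CG2
THR	HG22	H	0	0	CG2
THR	HG23	H	0	0	CG2
TRP	N	N	1	0	-
TRP	CA	C	1	0	-
TRP	C	C	0	0	-
TRP	O	O	0	0	-
TRP	CB	C	2	0	-
TRP	CG	C	0	1	-
TRP	CD1	C	1	1	-
TRP	CD2	C	0	1	-
TRP	NE1	N	1	1	-
TRP	CE2	C	0	1	-
TRP	CE3	C	1	1	-
TRP	CZ2	C	1	1	-
TRP	CZ3	C	1	1	-
TRP	CH2	C	1	1	-
TRP	H	H	0	0	N
TRP	HA	H	0	0	CA
TRP	HB2	H	0	0	CB
TRP	HB3	H	0	0	CB
TRP	HD1	H	0	0	CD1
TRP	HE1	H	0	0	NE1
TRP	HE3	H	0	0	CE3
TRP	HZ2	H	0	0	CZ2
TRP	HZ3	H	0	0	CZ3
TRP	HH2	H	0	0	CH2
TYR	N	N	1	0	-
TYR	CA	C	1	0	-
TYR	C	C	0	0	-
TYR	O	O	0	0	-
TYR	CB	C	2	0	-
TYR	CG	C	0	1	-
TYR	CD1	C	1	1	-
TYR	CD2	C	1	1	-
TYR	CE1	C	1	1	-
TYR	CE2	C	1	1	-
TYR	CZ	C	0	1	-
TYR	OH	O	1	0	-
TYR	H	H	0	0	N
TYR	HA	H	0	0	CA
TYR	HB2	H	0	0	CB
TYR	HB3	H	0	0	CB
TYR	HD1	H	0	0	CD1
TYR	HD2	H	0	0	CD2
TYR	HE1	H	0	0	CE1
TYR	HE2	H	0	0	CE2
TYR	HH	H	0	0	OH
VAL	N	N	1	0	-
VAL	CA	C	1	0	-
VAL	C	C	0	0	-
VAL	O	O	0	0	-
VAL	CB	C	1	0	-
VAL	CG1	C	3	0	-
VAL	CG2	C	3	0	-
VAL	H	H	0	0	N
VAL	HA	H	0	0	CA
VAL	HB	H	0	0	CB
VAL	HG11	H	0	0	CG1
VAL	HG12	H	0	0	CG1
VAL	HG13	H	0	0	CG1
VAL	HG21	H	0	0	CG2
VAL	HG22	H	0	0	CG2
VAL	HG23	H	0	0	CG2
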