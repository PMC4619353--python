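# Heavy-atom residue charge templates (elementary charges), hydrogen charges
# folded into the parent heavy atom. A coarse bond-increment-style set:
# formal charges are spread over the terminal polar group and the backbone
# amide carries a stronger dipole than the charmm-like set. Each residue sums
# to its formal charge.
# residue_name	atom_name	charge
ALA	N	-0.30
ALA	CA	0.30
ALA	C	0.57
ALA	O	-0.57
ALA	CB	0.00
ARG	N	-0.30
ARG	CA	0.30
ARG	C	0.57
ARG	O	-0.57
ARG	CB	0.00
ARG	CG	0.00
ARG	CD	0.20
ARG	NE	-0.10
ARG	CZ	0.50
ARG	NH1	0.20
ARG	NH2	0.20
ASN	N	-0.30
ASN	CA	0.30
ASN	C	0.57
ASN	O	-0.57
ASN	CB	0.00
ASN	CG	0.60
ASN	OD1	-0.60
ASN	ND2	0.00
ASP	N	-0.30
ASP	CA	0.30
ASP	C	0.57
ASP	O	-0.57
ASP	CB	0.00
ASP	CG	0.90
ASP	OD1	-0.95
ASP	OD2	-0.95
CYS	N	-0.30
CYS	CA	0.30
CYS	C	0.57
CYS	O	-0.57
CYS	CB	0.10
CYS	SG	-0.10
GLN	N	-0.30
GLN	CA	0.30
GLN	C	0.57
GLN	O	-0.57
GLN	CB	0.00
GLN	CG	0.00
GLN	CD	0.60
GLN	OE1	-0.60
GLN	NE2	0.00
GLU	N	-0.30
GLU	CA	0.30
GLU	C	0.57
GLU	O	-0.57
GLU	CB	0.00
GLU	CG	0.00
GLU	CD	0.90
GLU	OE1	-0.95
GLU	OE2	-0.95
GLY	N	-0.30
GLY	CA	0.30
GLY	C	0.57
GLY	O	-0.57
HIS	N	-0.30
HIS	CA	0.30
HIS	C	0.57
HIS	O	-0.57
HIS	CB	0.00
HIS	CG	0.00
HIS	ND1	-0.20
HIS	CD2	0.20
HIS	CE1	0.40
HIS	NE2	-0.40
ILE	N	-0.30
ILE	CA	0.30
ILE	C	0.57
ILE	O	-0.57
ILE	CB	0.00
ILE	CG1	0.00
ILE	CG2	0.00
ILE	CD1	0.00
LEU	N	-0.30
LEU	CA	0.30
LEU	C	0.57
LEU	O	-0.57
LEU	CB	0.00
LEU	CG	0.00
LEU	CD1	0.00
LEU	CD2	0.00
LYS	N	-0.30
LYS	CA	0.30
LYS	C	0.57
LYS	O	-0.57
LYS	CB	0.00
LYS	CG	0.00
LYS	CD	0.00
LYS	CE	0.10
LYS	NZ	0.90
MET	N	-0.30
MET	CA	0.30
MET	C	0.57
MET	O	-0.57
MET	CB	0.00
MET	CG	0.05
MET	SD	-0.10
MET	CE	0.05
PHE	N	-0.30
PHE	CA	0.30
PHE	C	0.57
PHE	O	-0.57
PHE	CB	0.00
PHE	CG	0.00
PHE	CD1	0.00
PHE	CD2	0.00
PHE	CE1	0.00
PHE	CE2	0.00
PHE	CZ	0.00
PRO	N	-0.30
PRO	CA	0.30
PRO	C	0.57
PRO	O	-0.57
PRO	CB	0.00
PRO	CG	0.00
PRO	CD	0.00
SER	N	-0.30
SER	CA	0.30
SER	C	0.57
SER	O	-0.57
SER	CB	0.20
SER	OG	-0.20
THR	N	-0.30
THR	CA	0.30
THR	C	0.57
THR	O	-0.57
THR	CB	0.20
THR	OG1	-0.20
THR	CG2	0.00
TRP	N	-0.30
TRP	CA	0.30
TRP	C	0.57
TRP	O	-0.57
TRP	CB	0.00
TRP	CG	0.00
TRP	CD1	0.10
TRP	NE1	-0.10
TRP	CE2	0.00
TRP	CD2	0.00
TRP	CE3	0.00
TRP	CZ2	0.00
TRP	CZ3	0.00
TRP	CH2	0.00
TYR	N	-0.30
TYR	CA	0.30
TYR	C	0.57
TYR	O	-0.57
TYR	CB	0.00
TYR	CG	0.00
TYR	CD1	0.00
TYR	CD2	0.00
TYR	CE1	0.00
TYR	CE2	0.00
TYR	CZ	0.15
TYR	OH	-0.15
VAL	N	-0.30
VAL	CA	0.30
VAL	C	0.57
VAL	O	-0.57
VAL	CB	0.00
VAL	CG1	0.00
VAL	CG2	0.00
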