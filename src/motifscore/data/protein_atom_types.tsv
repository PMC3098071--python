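# Residue/atom-name -> atom-type lookup for the 20 standard residues,
# terminal atoms and retained metal ions.  '*' matches any residue; an exact
# (residue, atom) row overrides the wildcard.
# residue	atom	code
*	N	NLB
*	CA	C3P
*	C	C2P
*	O	O2A
*	OXT	OLC
PRO	N	NLA
ALA	CB	C3N
ARG	CB	C3N
ARG	CG	C3N
ARG	CD	C3P
ARG	NE	NLC
ARG	CZ	C2P
ARG	NH1	NLC
ARG	NH2	NLC
ASN	CB	C3N
ASN	CG	C2P
ASN	OD1	O2A
ASN	ND2	NLB
ASP	CB	C3N
ASP	CG	C2P
ASP	OD1	OLC
ASP	OD2	OLC
CYS	CB	C3P
CYS	SG	S3N
GLN	CB	C3N
GLN	CG	C3N
GLN	CD	C2P
GLN	OE1	O2A
GLN	NE2	NLB
GLU	CB	C3N
GLU	CG	C3N
GLU	CD	C2P
GLU	OE1	OLC
GLU	OE2	OLC
HIS	CB	C3N
HIS	CG	CRP
HIS	ND1	NRE
HIS	CD2	CRP
HIS	CE1	CRP
HIS	NE2	NRE
ILE	CB	C3N
ILE	CG1	C3N
ILE	CG2	C3N
ILE	CD1	C3N
LEU	CB	C3N
LEU	CG	C3N
LEU	CD1	C3N
LEU	CD2	C3N
LYS	CB	C3N
LYS	CG	C3N
LYS	CD	C3N
LYS	CE	C3P
LYS	NZ	NLC
MET	CB	C3N
MET	CG	C3P
MET	SD	S3N
MET	CE	C3P
PHE	CB	C3N
PHE	CG	CRN
PHE	CD1	CRN
PHE	CD2	CRN
PHE	CE1	CRN
PHE	CE2	CRN
PHE	CZ	CRN
PRO	CB	C3N
PRO	CG	C3N
PRO	CD	C3P
SER	CB	C3P
SER	OG	O3B
THR	CB	C3P
THR	OG1	O3B
THR	CG2	C3N
TRP	CB	C3N
TRP	CG	CRN
TRP	CD1	CRP
TRP	CD2	CRN
TRP	NE1	NRE
TRP	CE2	CRP
TRP	CE3	CRN
TRP	CZ2	CRN
TRP	CZ3	CRN
TRP	CH2	CRN
TYR	CB	C3N
TYR	CG	CRN
TYR	CD1	CRN
TYR	CD2	CRN
TYR	CE1	CRN
TYR	CE2	CRN
TYR	CZ	CRP
TYR	OH	O3B
VAL	CB	C3N
VAL	CG1	C3N
VAL	CG2	C3N
ZN	ZN	MET
CA	CA	MET
MG	MG	MET
MN	MN	MET
FE	FE	MET
NI	NI	MET
CU	CU	MET
CO	CO	MET
CD	CD	MET
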