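# Pharmacophore categories per (residue, heavy atom).
# Categories: Hydrophobic Positive Negative HBondAcceptor HBondDonor Aromatic Sulfur Neutral
# Backbone amide N is a donor (except PRO); carbonyl O an acceptor; OXT carboxylate.
residue	atom	categories
ALA	N	HBondDonor
ALA	CA	Neutral
ALA	C	Neutral
ALA	O	HBondAcceptor
ALA	OXT	Negative;HBondAcceptor
ALA	CB	Hydrophobic
ARG	N	HBondDonor
ARG	CA	Neutral
ARG	C	Neutral
ARG	O	HBondAcceptor
ARG	OXT	Negative;HBondAcceptor
ARG	CB	Hydrophobic
ARG	CG	Hydrophobic
ARG	CD	Neutral
ARG	NE	Positive;HBondDonor
ARG	CZ	Positive
ARG	NH1	Positive;HBondDonor
ARG	NH2	Positive;HBondDonor
ASN	N	HBondDonor
ASN	CA	Neutral
ASN	C	Neutral
ASN	O	HBondAcceptor
ASN	OXT	Negative;HBondAcceptor
ASN	CB	Hydrophobic
ASN	CG	Neutral
ASN	OD1	HBondAcceptor
ASN	ND2	HBondDonor
ASP	N	HBondDonor
ASP	CA	Neutral
ASP	C	Neutral
ASP	O	HBondAcceptor
ASP	OXT	Negative;HBondAcceptor
ASP	CB	Hydrophobic
ASP	CG	Neutral
ASP	OD1	Negative;HBondAcceptor
ASP	OD2	Negative;HBondAcceptor
CYS	N	HBondDonor
CYS	CA	Neutral
CYS	C	Neutral
CYS	O	HBondAcceptor
CYS	OXT	Negative;HBondAcceptor
CYS	CB	Hydrophobic
CYS	SG	Sulfur
GLN	N	HBondDonor
GLN	CA	Neutral
GLN	C	Neutral
GLN	O	HBondAcceptor
GLN	OXT	Negative;HBondAcceptor
GLN	CB	Hydrophobic
GLN	CG	Hydrophobic
GLN	CD	Neutral
GLN	OE1	HBondAcceptor
GLN	NE2	HBondDonor
GLU	N	HBondDonor
GLU	CA	Neutral
GLU	C	Neutral
GLU	O	HBondAcceptor
GLU	OXT	Negative;HBondAcceptor
GLU	CB	Hydrophobic
GLU	CG	Hydrophobic
GLU	CD	Neutral
GLU	OE1	Negative;HBondAcceptor
GLU	OE2	Negative;HBondAcceptor
GLY	N	HBondDonor
GLY	CA	Neutral
GLY	C	Neutral
GLY	O	HBondAcceptor
GLY	OXT	Negative;HBondAcceptor
HIS	N	HBondDonor
HIS	CA	Neutral
HIS	C	Neutral
HIS	O	HBondAcceptor
HIS	OXT	Negative;HBondAcceptor
HIS	CB	Hydrophobic
HIS	CG	Aromatic
HIS	ND1	Aromatic;Positive;HBondDonor;HBondAcceptor
HIS	CD2	Aromatic
HIS	CE1	Aromatic
HIS	NE2	Aromatic;Positive;HBondDonor;HBondAcceptor
ILE	N	HBondDonor
ILE	CA	Neutral
ILE	C	Neutral
ILE	O	HBondAcceptor
ILE	OXT	Negative;HBondAcceptor
ILE	CB	Hydrophobic
ILE	CG1	Hydrophobic
ILE	CG2	Hydrophobic
ILE	CD1	Hydrophobic
LEU	N	HBondDonor
LEU	CA	Neutral
LEU	C	Neutral
LEU	O	HBondAcceptor
LEU	OXT	Negative;HBondAcceptor
LEU	CB	Hydrophobic
LEU	CG	Hydrophobic
LEU	CD1	Hydrophobic
LEU	CD2	Hydrophobic
LYS	N	HBondDonor
LYS	CA	Neutral
LYS	C	Neutral
LYS	O	HBondAcceptor
LYS	OXT	Negative;HBondAcceptor
LYS	CB	Hydrophobic
LYS	CG	Hydrophobic
LYS	CD	Hydrophobic
LYS	CE	Neutral
LYS	NZ	Positive;HBondDonor
MET	N	HBondDonor
MET	CA	Neutral
MET	C	Neutral
MET	O	HBondAcceptor
MET	OXT	Negative;HBondAcceptor
MET	CB	Hydrophobic
MET	CG	Hydrophobic
MET	SD	Sulfur
MET	CE	Hydrophobic
PHE	N	HBondDonor
PHE	CA	Neutral
PHE	C	Neutral
PHE	O	HBondAcceptor
PHE	OXT	Negative;HBondAcceptor
PHE	CB	Hydrophobic
PHE	CG	Aromatic;Hydrophobic
PHE	CD1	Aromatic;Hydrophobic
PHE	CD2	Aromatic;Hydrophobic
PHE	CE1	Aromatic;Hydrophobic
PHE	CE2	Aromatic;Hydrophobic
PHE	CZ	Aromatic;Hydrophobic
PRO	N	Neutral
PRO	CA	Neutral
PRO	C	Neutral
PRO	O	HBondAcceptor
PRO	OXT	Negative;HBondAcceptor
PRO	CB	Hydrophobic
PRO	CG	Hydrophobic
PRO	CD	Neutral
SER	N	HBondDonor
SER	CA	Neutral
SER	C	Neutral
SER	O	HBondAcceptor
SER	OXT	Negative;HBondAcceptor
SER	CB	Neutral
SER	OG	HBondDonor;HBondAcceptor
THR	N	HBondDonor
THR	CA	Neutral
THR	C	Neutral
THR	O	HBondAcceptor
THR	OXT	Negative;HBondAcceptor
THR	CB	Neutral
THR	OG1	HBondDonor;HBondAcceptor
THR	CG2	Hydrophobic
TRP	N	HBondDonor
TRP	CA	Neutral
TRP	C	Neutral
TRP	O	HBondAcceptor
TRP	OXT	Negative;HBondAcceptor
TRP	CB	Hydrophobic
TRP	CG	Aromatic;Hydrophobic
TRP	CD1	Aromatic
TRP	CD2	Aromatic;Hydrophobic
TRP	NE1	Aromatic;HBondDonor
TRP	CE2	Aromatic;Hydrophobic
TRP	CE3	Aromatic;Hydrophobic
TRP	CZ2	Aromatic;Hydrophobic
TRP	CZ3	Aromatic;Hydrophobic
TRP	CH2	Aromatic;Hydrophobic
TYR	N	HBondDonor
TYR	CA	Neutral
TYR	C	Neutral
TYR	O	HBondAcceptor
TYR	OXT	Negative;HBondAcceptor
TYR	CB	Hydrophobic
TYR	CG	Aromatic;Hydrophobic
TYR	CD1	Aromatic;Hydrophobic
TYR	CD2	Aromatic;Hydrophobic
TYR	CE1	Aromatic;Hydrophobic
TYR	CE2	Aromatic;Hydrophobic
TYR	CZ	Aromatic;Hydrophobic
TYR	OH	HBondDonor;HBondAcceptor
VAL	N	HBondDonor
VAL	CA	Neutral
VAL	C	Neutral
VAL	O	HBondAcceptor
VAL	OXT	Negative;HBondAcceptor
VAL	CB	Hydrophobic
VAL	CG1	Hydrophobic
VAL	CG2	Hydrophobic
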