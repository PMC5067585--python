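# Residue chemistry knowledge base (PDB v3 atom nomenclature).
# Columns: res_name <TAB> role <TAB> atom <TAB> partner_hydrogens
# Roles: donor (heavy atom + '|'-separated bonded hydrogens), acceptor,
#        sidechain (heavy atoms; side-chain hydrogens are attached by the
#        backbone-exclusion rule in code), positive, negative, aromatic,
#        remove_donor (mask a wildcard donor, e.g. proline backbone N).
# '*' rows apply to every residue listed in this table; an atom value of '-'
# declares a residue with no entries for that role (glycine side chain).
*	donor	N	H|H1|H2|H3
*	acceptor	O	-
*	acceptor	OXT	-
ALA	sidechain	CB	-
ARG	donor	NE	HE
ARG	donor	NH1	HH11|HH12
ARG	donor	NH2	HH21|HH22
ARG	positive	NE	-
ARG	positive	NH1	-
ARG	positive	NH2	-
ARG	positive	CZ	-
ARG	sidechain	CB	-
ARG	sidechain	CG	-
ARG	sidechain	CD	-
ARG	sidechain	NE	-
ARG	sidechain	CZ	-
ARG	sidechain	NH1	-
ARG	sidechain	NH2	-
ASN	donor	ND2	HD21|HD22
ASN	acceptor	OD1	-
ASN	sidechain	CB	-
ASN	sidechain	CG	-
ASN	sidechain	OD1	-
ASN	sidechain	ND2	-
ASP	acceptor	OD1	-
ASP	acceptor	OD2	-
ASP	negative	OD1	-
ASP	negative	OD2	-
ASP	negative	CG	-
ASP	sidechain	CB	-
ASP	sidechain	CG	-
ASP	sidechain	OD1	-
ASP	sidechain	OD2	-
CYS	donor	SG	HG
CYS	acceptor	SG	-
CYS	sidechain	CB	-
CYS	sidechain	SG	-
GLN	donor	NE2	HE21|HE22
GLN	acceptor	OE1	-
GLN	sidechain	CB	-
GLN	sidechain	CG	-
GLN	sidechain	CD	-
GLN	sidechain	OE1	-
GLN	sidechain	NE2	-
GLU	acceptor	OE1	-
GLU	acceptor	OE2	-
GLU	negative	OE1	-
GLU	negative	OE2	-
GLU	negative	CD	-
GLU	sidechain	CB	-
GLU	sidechain	CG	-
GLU	sidechain	CD	-
GLU	sidechain	OE1	-
GLU	sidechain	OE2	-
GLY	sidechain	-	-
HIS	donor	ND1	HD1
HIS	donor	NE2	HE2
HIS	acceptor	ND1	-
HIS	acceptor	NE2	-
HIS	positive	ND1	-
HIS	positive	NE2	-
HIS	aromatic	CG	-
HIS	aromatic	ND1	-
HIS	aromatic	CD2	-
HIS	aromatic	CE1	-
HIS	aromatic	NE2	-
HIS	sidechain	CB	-
HIS	sidechain	CG	-
HIS	sidechain	ND1	-
HIS	sidechain	CD2	-
HIS	sidechain	CE1	-
HIS	sidechain	NE2	-
ILE	sidechain	CB	-
ILE	sidechain	CG1	-
ILE	sidechain	CG2	-
ILE	sidechain	CD1	-
LEU	sidechain	CB	-
LEU	sidechain	CG	-
LEU	sidechain	CD1	-
LEU	sidechain	CD2	-
LYS	donor	NZ	HZ1|HZ2|HZ3
LYS	positive	NZ	-
LYS	sidechain	CB	-
LYS	sidechain	CG	-
LYS	sidechain	CD	-
LYS	sidechain	CE	-
LYS	sidechain	NZ	-
MET	acceptor	SD	-
MET	sidechain	CB	-
MET	sidechain	CG	-
MET	sidechain	SD	-
MET	sidechain	CE	-
PHE	aromatic	CG	-
PHE	aromatic	CD1	-
PHE	aromatic	CD2	-
PHE	aromatic	CE1	-
PHE	aromatic	CE2	-
PHE	aromatic	CZ	-
PHE	sidechain	CB	-
PHE	sidechain	CG	-
PHE	sidechain	CD1	-
PHE	sidechain	CD2	-
PHE	sidechain	CE1	-
PHE	sidechain	CE2	-
PHE	sidechain	CZ	-
PRO	remove_donor	N	-
PRO	sidechain	CB	-
PRO	sidechain	CG	-
PRO	sidechain	CD	-
SER	donor	OG	HG
SER	acceptor	OG	-
SER	sidechain	CB	-
SER	sidechain	OG	-
THR	donor	OG1	HG1
THR	acceptor	OG1	-
THR	sidechain	CB	-
THR	sidechain	OG1	-
THR	sidechain	CG2	-
TRP	donor	NE1	HE1
TRP	aromatic	CG	-
TRP	aromatic	CD1	-
TRP	aromatic	CD2	-
TRP	aromatic	NE1	-
TRP	aromatic	CE2	-
TRP	aromatic	CE3	-
TRP	aromatic	CZ2	-
TRP	aromatic	CZ3	-
TRP	aromatic	CH2	-
TRP	sidechain	CB	-
TRP	sidechain	CG	-
TRP	sidechain	CD1	-
TRP	sidechain	CD2	-
TRP	sidechain	NE1	-
TRP	sidechain	CE2	-
TRP	sidechain	CE3	-
TRP	sidechain	CZ2	-
TRP	sidechain	CZ3	-
TRP	sidechain	CH2	-
TYR	donor	OH	HH
TYR	acceptor	OH	-
TYR	aromatic	CG	-
TYR	aromatic	CD1	-
TYR	aromatic	CD2	-
TYR	aromatic	CE1	-
TYR	aromatic	CE2	-
TYR	aromatic	CZ	-
TYR	sidechain	CB	-
TYR	sidechain	CG	-
TYR	sidechain	CD1	-
TYR	sidechain	CD2	-
TYR	sidechain	CE1	-
TYR	sidechain	CE2	-
TYR	sidechain	CZ	-
TYR	sidechain	OH	-
VAL	sidechain	CB	-
VAL	sidechain	CG1	-
VAL	sidechain	CG2	-
PTR	acceptor	O1P	-
PTR	acceptor	O2P	-
PTR	acceptor	O3P	-
PTR	negative	O1P	-
PTR	negative	O2P	-
PTR	negative	O3P	-
PTR	negative	P	-
PTR	aromatic	CG	-
PTR	aromatic	CD1	-
PTR	aromatic	CD2	-
PTR	aromatic	CE1	-
PTR	aromatic	CE2	-
PTR	aromatic	CZ	-
PTR	sidechain	CB	-
PTR	sidechain	CG	-
PTR	sidechain	CD1	-
PTR	sidechain	CD2	-
PTR	sidechain	CE1	-
PTR	sidechain	CE2	-
PTR	sidechain	CZ	-
PTR	sidechain	OH	-
PTR	sidechain	P	-
PTR	sidechain	O1P	-
PTR	sidechain	O2P	-
PTR	sidechain	O3P	-
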