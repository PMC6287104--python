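residue,atom,charge,radius
ALA,N,-0.40,1.50
ALA,H,0.40,1.00
ALA,CA,0.00,1.70
ALA,HA,0.00,1.00
ALA,C,0.55,1.70
ALA,O,-0.55,1.40
ARG,N,-0.40,1.50
ARG,H,0.40,1.00
ARG,CA,0.00,1.70
ARG,HA,0.00,1.00
ARG,C,0.55,1.70
ARG,O,-0.55,1.40
ASN,N,-0.40,1.50
ASN,H,0.40,1.00
ASN,CA,0.00,1.70
ASN,HA,0.00,1.00
ASN,C,0.55,1.70
ASN,O,-0.55,1.40
ASP,N,-0.40,1.50
ASP,H,0.40,1.00
ASP,CA,0.00,1.70
ASP,HA,0.00,1.00
ASP,C,0.55,1.70
ASP,O,-0.55,1.40
CYS,N,-0.40,1.50
CYS,H,0.40,1.00
CYS,CA,0.00,1.70
CYS,HA,0.00,1.00
CYS,C,0.55,1.70
CYS,O,-0.55,1.40
GLN,N,-0.40,1.50
GLN,H,0.40,1.00
GLN,CA,0.00,1.70
GLN,HA,0.00,1.00
GLN,C,0.55,1.70
GLN,O,-0.55,1.40
GLU,N,-0.40,1.50
GLU,H,0.40,1.00
GLU,CA,0.00,1.70
GLU,HA,0.00,1.00
GLU,C,0.55,1.70
GLU,O,-0.55,1.40
GLY,N,-0.40,1.50
GLY,H,0.40,1.00
GLY,CA,0.00,1.70
GLY,HA,0.00,1.00
GLY,C,0.55,1.70
GLY,O,-0.55,1.40
HIS,N,-0.40,1.50
HIS,H,0.40,1.00
HIS,CA,0.00,1.70
HIS,HA,0.00,1.00
HIS,C,0.55,1.70
HIS,O,-0.55,1.40
ILE,N,-0.40,1.50
ILE,H,0.40,1.00
ILE,CA,0.00,1.70
ILE,HA,0.00,1.00
ILE,C,0.55,1.70
ILE,O,-0.55,1.40
LEU,N,-0.40,1.50
LEU,H,0.40,1.00
LEU,CA,0.00,1.70
LEU,HA,0.00,1.00
LEU,C,0.55,1.70
LEU,O,-0.55,1.40
LYS,N,-0.40,1.50
LYS,H,0.40,1.00
LYS,CA,0.00,1.70
LYS,HA,0.00,1.00
LYS,C,0.55,1.70
LYS,O,-0.55,1.40
MET,N,-0.40,1.50
MET,H,0.40,1.00
MET,CA,0.00,1.70
MET,HA,0.00,1.00
MET,C,0.55,1.70
MET,O,-0.55,1.40
PHE,N,-0.40,1.50
PHE,H,0.40,1.00
PHE,CA,0.00,1.70
PHE,HA,0.00,1.00
PHE,C,0.55,1.70
PHE,O,-0.55,1.40
PRO,N,-0.25,1.50
PRO,CA,0.00,1.70
PRO,HA,0.00,1.00
PRO,C,0.55,1.70
PRO,O,-0.55,1.40
SER,N,-0.40,1.50
SER,H,0.40,1.00
SER,CA,0.00,1.70
SER,HA,0.00,1.00
SER,C,0.55,1.70
SER,O,-0.55,1.40
THR,N,-0.40,1.50
THR,H,0.40,1.00
THR,CA,0.00,1.70
THR,HA,0.00,1.00
THR,C,0.55,1.70
THR,O,-0.55,1.40
TRP,N,-0.40,1.50
TRP,H,0.40,1.00
TRP,CA,0.00,1.70
TRP,HA,0.00,1.00
TRP,C,0.55,1.70
TRP,O,-0.55,1.40
TYR,N,-0.40,1.50
TYR,H,0.40,1.00
TYR,CA,0.00,1.70
TYR,HA,0.00,1.00
TYR,C,0.55,1.70
TYR,O,-0.55,1.40
VAL,N,-0.40,1.50
VAL,H,0.40,1.00
VAL,CA,0.00,1.70
VAL,HA,0.00,1.00
VAL,C,0.55,1.70
VAL,O,-0.55,1.40
ALA,CB,0.00,1.70
ALA,HB1,0.00,1.00
ALA,HB2,0.00,1.00
ALA,HB3,0.00,1.00
ARG,CB,0.00,1.70
ARG,CG,0.00,1.70
ARG,CD,0.00,1.70
ARG,NE,-0.40,1.50
ARG,HE,0.40,1.00
ARG,CZ,0.60,1.70
ARG,NH1,-0.60,1.50
ARG,HH11,0.40,1.00
ARG,HH12,0.40,1.00
ARG,NH2,-0.60,1.50
ARG,HH21,0.40,1.00
ARG,HH22,0.40,1.00
ASN,CB,0.00,1.70
ASN,CG,0.55,1.70
ASN,OD1,-0.55,1.40
ASN,ND2,-0.78,1.50
ASN,HD21,0.39,1.00
ASN,HD22,0.39,1.00
ASP,CB,0.00,1.70
ASP,CG,0.10,1.70
ASP,OD1,-0.55,1.40
ASP,OD2,-0.55,1.40
CYS,CB,0.00,1.70
CYS,SG,-0.33,1.85
CYS,HG,0.33,1.00
GLN,CB,0.00,1.70
GLN,CG,0.00,1.70
GLN,CD,0.55,1.70
GLN,OE1,-0.55,1.40
GLN,NE2,-0.78,1.50
GLN,HE21,0.39,1.00
GLN,HE22,0.39,1.00
GLU,CB,0.00,1.70
GLU,CG,0.00,1.70
GLU,CD,0.10,1.70
GLU,OE1,-0.55,1.40
GLU,OE2,-0.55,1.40
GLY,HA2,0.00,1.00
GLY,HA3,0.00,1.00
HIS,CB,0.00,1.70
HIS,CG,0.10,1.70
HIS,ND1,-0.40,1.50
HIS,HD1,0.40,1.00
HIS,CD2,0.10,1.70
HIS,CE1,0.20,1.70
HIS,NE2,-0.40,1.50
ILE,CB,0.00,1.70
ILE,CG1,0.00,1.70
ILE,CG2,0.00,1.70
ILE,CD1,0.00,1.70
LEU,CB,0.00,1.70
LEU,CG,0.00,1.70
LEU,CD1,0.00,1.70
LEU,CD2,0.00,1.70
LYS,CB,0.00,1.70
LYS,CG,0.00,1.70
LYS,CD,0.00,1.70
LYS,CE,0.20,1.70
LYS,NZ,-0.40,1.50
LYS,HZ1,0.40,1.00
LYS,HZ2,0.40,1.00
LYS,HZ3,0.40,1.00
MET,CB,0.00,1.70
MET,CG,0.06,1.70
MET,SD,-0.12,1.85
MET,CE,0.06,1.70
PHE,CB,0.00,1.70
PHE,CG,0.00,1.70
PHE,CD1,0.00,1.70
PHE,CD2,0.00,1.70
PHE,CE1,0.00,1.70
PHE,CE2,0.00,1.70
PHE,CZ,0.00,1.70
PRO,CB,0.00,1.70
PRO,CG,0.00,1.70
PRO,CD,0.25,1.70
SER,CB,0.05,1.70
SER,OG,-0.49,1.40
SER,HG,0.44,1.00
THR,CB,0.05,1.70
THR,OG1,-0.49,1.40
THR,HG1,0.44,1.00
THR,CG2,0.00,1.70
TRP,CB,0.00,1.70
TRP,CG,0.00,1.70
TRP,CD1,0.00,1.70
TRP,CD2,0.00,1.70
TRP,NE1,-0.40,1.50
TRP,HE1,0.40,1.00
TRP,CE2,0.00,1.70
TRP,CE3,0.00,1.70
TRP,CZ2,0.00,1.70
TRP,CZ3,0.00,1.70
TRP,CH2,0.00,1.70
TYR,CB,0.00,1.70
TYR,CG,0.00,1.70
TYR,CD1,0.00,1.70
TYR,CD2,0.00,1.70
TYR,CE1,0.00,1.70
TYR,CE2,0.00,1.70
TYR,CZ,0.05,1.70
TYR,OH,-0.49,1.40
TYR,HH,0.44,1.00
VAL,CB,0.00,1.70
VAL,CG1,0.00,1.70
VAL,CG2,0.00,1.70
ACE,CH3,0.00,1.70
ACE,HH31,0.00,1.00
ACE,HH32,0.00,1.00
ACE,HH33,0.00,1.00
ACE,C,0.55,1.70
ACE,O,-0.55,1.40
NME,N,-0.40,1.50
NME,H,0.40,1.00
NME,CH3,0.00,1.70
NME,HH31,0.00,1.00
NME,HH32,0.00,1.00
NME,HH33,0.00,1.00
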