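# Side-chain analogue transfer free energies, water -> cyclohexane (kcal/mol).
# Radzicka A & Wolfenden R (1988) Biochemistry 27:1664-1670. Positive = hydrophobic.
# Proline has no side-chain analogue in this scale and is omitted.
residue,one_letter,value_kcal_mol
ALA,A,1.81
ARG,R,-14.92
ASN,N,-6.64
ASP,D,-8.72
CYS,C,1.28
GLN,Q,-5.54
GLU,E,-6.81
GLY,G,0.94
HIS,H,-4.66
ILE,I,4.92
LEU,L,4.92
LYS,K,-5.55
MET,M,2.35
PHE,F,2.98
SER,S,-3.40
THR,T,-2.57
TRP,W,2.33
TYR,Y,-0.14
VAL,V,4.04
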