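# Side-chain accessible surface areas (A^2) in the Gly-X-Gly standard state.
# Miller S, Janin J, Lesk AM & Chothia C (1987) J Mol Biol 196:641-656.
residue,one_letter,value_A2
ALA,A,67
ARG,R,196
ASN,N,113
ASP,D,106
CYS,C,104
GLN,Q,144
GLU,E,138
GLY,G,1
HIS,H,151
ILE,I,140
LEU,L,137
LYS,K,167
MET,M,160
PHE,F,175
PRO,P,105
SER,S,80
THR,T,102
TRP,W,217
TYR,Y,187
VAL,V,117
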