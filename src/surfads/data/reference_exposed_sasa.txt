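# reference solvent-exposed side-chain SASA per residue, nm^2
# provenance: Miller, Janin, Lesk & Chothia, J. Mol. Biol. 196, 641 (1987),
# standard-state side-chain areas in Gly-X-Gly tripeptides.
# GLY has no heavy side chain; assigned 0.50 nm^2, the exposed area of Gly
# in an Ala-Gly-Ala trimer; it never enters SAP because R_h(GLY) = 0.
# columns: residue  sasa_nm2  comment
ALA  0.67  alanine
ARG  1.96  arginine
ASN  1.13  asparagine
ASP  1.06  aspartate
CYS  1.04  cysteine
GLN  1.44  glutamine
GLU  1.38  glutamate
GLY  0.50  glycine (assigned, see header)
HIS  1.51  histidine
ILE  1.40  isoleucine
LEU  1.37  leucine
LYS  1.67  lysine
MET  1.60  methionine
PHE  1.75  phenylalanine
PRO  1.05  proline
SER  0.80  serine
THR  1.02  threonine
TRP  2.17  tryptophan
TYR  1.87  tyrosine
VAL  1.17  valine
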