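# residue hydrophobicity, Black & Mould (Anal. Biochem. 193, 72, 1991)
# normalized scale shifted additively by -0.501 so that GLY = 0
# columns: residue  R_h  comment
ALA   0.115  alanine
ARG  -0.501  arginine
ASN  -0.265  asparagine
ASP  -0.473  aspartate
CYS   0.179  cysteine
GLN  -0.250  glutamine
GLU  -0.458  glutamate
GLY   0.000  glycine (zero by construction)
HIS  -0.336  histidine
ILE   0.442  isoleucine
LEU   0.442  leucine
LYS  -0.218  lysine
MET   0.237  methionine
PHE   0.499  phenylalanine
PRO   0.210  proline
SER  -0.142  serine
THR  -0.051  threonine
TRP   0.377  tryptophan
TYR   0.379  tyrosine
VAL   0.324  valine
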