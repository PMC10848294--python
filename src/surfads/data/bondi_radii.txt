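# van der Waals radii by element, nm
# provenance: Bondi, J. Phys. Chem. 68, 441 (1964)
# columns: element  radius_nm  comment
H   0.120   hydrogen
C   0.170   carbon
N   0.155   nitrogen
O   0.152   oxygen
S   0.180   sulfur
P   0.180   phosphorus
F   0.147   fluorine
CL  0.175   chlorine
BR  0.185   bromine
I   0.198   iodine
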