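# Residue classes for LRR consensus codes.  Key = one-letter code used in
# the consensus string, value = string of allowed residues ("*" = any of
# the 20 standard residues).  Lowercase codes denote weaker constraints by
# LRR-literature convention; `z` matches anything but is tracked apart
# from `x` so alternative tables can constrain it.
L: "LIVMF"
N: "NTS"
C: "C"
F: "FYWL"
g: "GAS"
o: "AVLIMFWCGP"
p: "STNQYHKRDE"
z: "*"
x: "*"
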