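# RNA/RNA nearest-neighbor Watson-Crick stack free energies, dG37 (kcal/mol)
# Unified Turner-lab parameter set (Xia et al. 1998 / Turner 2004 rules).
# A stack 5'-XY-3' is the dinucleotide on one strand of a fully paired
# duplex; by duplex symmetry dG(XY) == dG(reverse complement of XY).
# version: 1
stack	dg37
AA	-0.93
AU	-1.10
AC	-2.24
AG	-2.08
UA	-1.33
UU	-0.93
UC	-2.35
UG	-2.11
CA	-2.11
CU	-2.08
CC	-3.26
CG	-2.36
GA	-2.35
GU	-2.24
GC	-3.42
GG	-3.26
# non-stack terms
init	4.09
terminal_AU	0.45
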