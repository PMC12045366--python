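# Average-mass table (g/mol) for fully modified oligonucleotide strands.
# version: 1
#
# Residue masses are average masses of internal phosphodiester residues
# (ribonucleoside 5'-monophosphate minus H2O): A 329.21, C 305.18,
# G 345.21, U 306.17. Sugar deltas: 2'-O-methyl adds CH2 (+14.03);
# 2'-fluoro swaps 2'-OH for F (-17.01 + 19.00 = +1.98). A phosphorothioate
# linkage swaps one non-bridging O for S (+16.06).
#
# Strand assembly rule: mass = sum(residue + sugar_delta) + n_PS * PS
# + water (free 3'-OH of the chain) + five_prime delta + three_prime delta.
# The residue sum corresponds to a 5'-phosphate strand, so five_prime OH
# removes HPO3 (-79.98) and vinylphosphonate replaces the bridging 5'-O
# with CH=CH (+C2H2 - O = +10.04). three_prime cholesterol_TEG is the
# documented-estimate mass added by a cholesteryl-tetraethylene-glycol
# phosphodiester conjugate; linker_attachment is the condensation
# correction (-H2O) for joining the strand to a branching linker.
# tetraethylene_glycol_branch is TEG (194.23) plus two phosphodiester
# bridges (2 x (79.98 - 18.02)), added once per divalent construct.
kind	key	value
residue	A	329.21
residue	C	305.18
residue	G	345.21
residue	U	306.17
sugar_delta	ribo	0.00
sugar_delta	2OMe	14.03
sugar_delta	2F	1.98
linkage_delta	PS	16.06
terminal	water	18.02
five_prime	OH	-79.98
five_prime	phosphate	0.00
five_prime	vinylphosphonate	10.04
three_prime	OH	0.00
three_prime	cholesterol_TEG	661.00
three_prime	linker_attachment	-18.02
linker	none	0.00
linker	tetraethylene_glycol_branch	318.15
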