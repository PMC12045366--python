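# Synthetic stand-in for the divalent scaffold-2 construct (the study's
# own strand sequences are not public). Scaffold 2 is the
# 2'-O-methyl-rich pattern (~76% 2'-O-methyl over the duplex) with
# sparse 2'-F positions, phosphorothioate ends, 5'-vinylphosphonate
# guide, and two passengers joined by a tetraethylene glycol branch.
name: divalent_1764_S2_synthetic
form: divalent
linker: tetraethylene_glycol_branch
guide:
  strand: "mU# fU# mA mU mC fG mA mA mG fC mU mC mA fG mU fC mG mA# mU# mU"
  five_prime: vinylphosphonate
  three_prime: OH
passenger:
  strand: "mG# mA# fC mU mG mA fG mC fU mU fC mG mA mU mA mA"
  five_prime: OH
  three_prime: linker_attachment
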