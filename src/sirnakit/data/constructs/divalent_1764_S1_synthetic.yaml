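# Synthetic stand-in for the divalent scaffold-1 construct (the study's
# own strand sequences are not public). The modification pattern follows
# the scaffold-1 style: alternating 2'-F / 2'-O-methyl guide body
# (~59% 2'-O-methyl over the duplex), phosphorothioate ends,
# 5'-vinylphosphonate guide, and two passengers joined by a
# tetraethylene glycol branch.
name: divalent_1764_S1_synthetic
form: divalent
linker: tetraethylene_glycol_branch
guide:
  strand: "mU# fU# mA fU mC fG mA fA mG fC mU fC mA fG mU fC mG fA# mU# mU"
  five_prime: vinylphosphonate
  three_prime: OH
passenger:
  strand: "mG# fA# mC fU mG fA mG fC mU fU mC fG mA mU mA mA"
  five_prime: OH
  three_prime: linker_attachment
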