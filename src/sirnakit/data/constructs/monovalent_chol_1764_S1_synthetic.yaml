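# Synthetic stand-in for a cholesterol-conjugated monovalent screen
# compound in the scaffold-1 modification pattern: the passenger 3'
# terminus carries a cholesteryl-TEG conjugate for gymnotic uptake.
name: monovalent_chol_1764_S1_synthetic
form: monovalent
linker: none
guide:
  strand: "mU# fU# mA fU mC fG mA fA mG fC mU fC mA fG mU fC mG fA# mU# mU"
  five_prime: phosphate
  three_prime: OH
passenger:
  strand: "mG# fA# mC fU mG fA mG fC mU fU mC fG mA mU mA mA"
  five_prime: OH
  three_prime: cholesterol_TEG
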