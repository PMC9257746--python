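group,e_h_j_per_mol,note
hydroxyl,20000,aliphatic or phenolic -OH
carboxylic_acid,10000,-COOH
ester,7000,-COO-
ether,3000,-O-
ketone,2000,">C=O"
aldehyde,4500,-CHO
primary_amine,8400,-NH2
secondary_amine,3100,>NH
tertiary_amine,800,>N-
amide,8000,-C(=O)N<
nitrile,2500,-CN
nitro,1500,-NO2
fluoride,500,-F
chloride,400,-Cl
sulfone,1100,>SO2
thiol,2000,-SH
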