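name,role,mw,hbd,hba,delta_h_hansen,mu,smiles
bisVCap,coformer,278.40,0,4,,,CC(N1CCCCCC1=O)/C=C/N2CCCCCC2=O
benzocaine,API,165.19,2,3,,,CCOC(=O)c1ccc(N)cc1
caffeine,API,194.19,0,6,,,Cn1cnc2c1c(=O)n(C)c(=O)n2C
carbamazepine,API,236.27,2,3,,,NC(=O)N1c2ccccc2C=Cc2ccccc21
carisoprodol,API,260.33,3,6,,,CCCC(C)(COC(N)=O)COC(=O)NC(C)C
dopamine,API,153.18,4,3,,,NCCc1ccc(O)c(O)c1
isoniazid,API,137.14,3,4,,,NNC(=O)c1ccncc1
valsartan,API,435.53,2,8,,,CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(C)C)C(=O)O
aspirin,API,180.16,1,4,,,CC(=O)Oc1ccccc1C(=O)O
chloramphenicol,API,323.13,3,7,,,OCC(NC(=O)C(Cl)Cl)C(O)c1ccc([N+](=O)[O-])cc1
chlorpropamide,API,276.75,2,5,,,CCCNC(=O)NS(=O)(=O)c1ccc(Cl)cc1
famotidine,API,337.46,8,9,,,NC(N)=Nc1nc(CSCCC(N)=NS(N)(=O)=O)cs1
flurbiprofen,API,244.26,1,2,,,CC(C(=O)O)c1ccc(-c2ccccc2)c(F)c1
furosemide,API,330.75,4,7,,,NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
indomethacin,API,357.79,1,5,,,COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
ketoprofen,API,254.28,1,3,,,CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1
mebendazole,API,295.30,2,6,,,COC(=O)Nc1nc2cc(C(=O)c3ccccc3)ccc2[nH]1
paracetamol,API,151.16,2,3,,,CC(=O)Nc1ccc(O)cc1
phenobarbital,API,232.24,2,5,,,CCC1(c2ccccc2)C(=O)NC(=O)NC1=O
piroxicam,API,331.35,2,7,,,CN1C(C(=O)Nc2ccccn2)=C(O)c2ccccc2S1(=O)=O
simvastatin,API,418.57,1,5,,,CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C12
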