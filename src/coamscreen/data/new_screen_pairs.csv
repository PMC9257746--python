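api,coformer,dh_mix,dh_hb,experimental_label,label_short,predicted_label,coam_value
aspirin,bisVCap,,,Y,ASPR,Y,0.864
chloramphenicol,bisVCap,,,Y,CHPL,Y,0.682
chlorpropamide,bisVCap,,,Y,CHPD,Y,0.500
famotidine,bisVCap,,,D,FAMO,N,0.463
flurbiprofen,bisVCap,,,Y,FLURB,Y,1.096
furosemide,bisVCap,,,Y,FUR,Y,1.091
indomethacin,bisVCap,,,Y,INDO,Y,1.142
ketoprofen,bisVCap,,,Y,KETO,Y,0.833
mebendazole,bisVCap,,,D,MEB,Y,0.556
paracetamol,bisVCap,,,Y,PARA,N,0.450
phenobarbital,bisVCap,,,Y,PHB,Y,0.588
piroxicam,bisVCap,,,D,PIRO,N,0.443
simvastatin,bisVCap,,,Y,SIM,Y,0.751
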