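api,coformer,dh_mix,dh_hb,experimental_label,label_short,predicted_label,coam_value
benzocaine,bisVCap,,,N,BENZ,N,
caffeine,bisVCap,,,N,CAFF,N,
carbamazepine,bisVCap,,,Y,CARB,N,
carisoprodol,bisVCap,,,Y,CARI,N,
dopamine,bisVCap,,,N,DOPA,N,
isoniazid,bisVCap,,,N,ISON,N,
valsartan,bisVCap,,,Y,VALS,Y,
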