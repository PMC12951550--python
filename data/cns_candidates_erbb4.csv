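compound_id,name,delta_g_pred,bbb,pgp_sub,pgp_inh
DB12016,Ponesimod,-9.62,0.95,0.00,0.14
DB13643,Loprazolam,-9.61,1.00,0.00,0.07
DB11805,Saracatinib,-9.49,0.96,0.00,0.45
DB01222,Budesonide,-9.49,1.00,0.02,0.05
DB15489,Mexazolam,-9.34,1.00,0.04,0.45
DB05410,NCX 1022,-9.33,0.81,0.00,0.04
DB07117,,-9.31,1.00,0.01,0.00
DB07249,,-9.31,0.96,0.00,0.04
DB00248,Cabergoline,-9.29,1.00,0.00,0.01
DB09295,Talniflumate,-9.29,0.96,0.00,0.00
DB09383,Meprednisone,-9.28,0.82,0.00,0.46
DB13208,Prednylidene,-9.25,0.79,0.01,0.05
DB12549,Pyrazoloacridine,-9.21,0.99,0.07,0.15
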