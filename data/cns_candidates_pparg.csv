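compound_id,name,delta_g_pred,bbb,pgp_sub,pgp_inh
DB07242,,-9.17,1.00,0.02,0.39
DB00248,Cabergoline,-9.17,1.00,0.00,0.01
DB01218,Halofantrine,-9.09,0.85,0.04,0.15
DB02132,Zenarestat,-9.07,0.72,0.00,0.00
DB15367,LY-2623091,-8.99,1.00,0.01,0.21
DB07270,,-8.95,0.71,0.00,0.16
DB11794,Berzosertib,-8.95,0.86,0.00,0.04
DB13937,LGD-3303,-8.91,0.90,0.00,0.02
DB07218,,-8.88,0.94,0.01,0.28
DB01611,Hydroxychloroquine,-8.87,0.87,0.18,0.31
DB14970,Alobresib,-8.82,0.99,0.00,0.00
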