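compound_id,name,delta_g_pred,bbb,pgp_sub,pgp_inh
DB02022,Toxopyrimidine,-9.7,0.92,0.19,0.00
DB13414,Fenyramidol,-9.61,0.83,0.07,0.01
DB12740,CC-115,-9.35,0.98,0.02,0.01
DB12485,Pimonidazole,-9.34,0.78,0.02,0.00
DB13069,Nimustine,-9.3,0.96,0.02,0.01
DB12522,Toreforant,-9.28,0.98,0.00,0.10
DB07244,,-9.28,0.94,0.08,0.10
DB12177,Eplivanserin,-9.26,0.76,0.00,0.10
DB08707,,-9.24,1.00,0.00,0.13
DB16954,Ezeprogind,-9.24,1.00,0.20,0.18
DB15091,Upadacitinib,-9.23,0.79,0.14,0.18
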