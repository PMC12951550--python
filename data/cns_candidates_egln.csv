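compound_id,name,delta_g_pred,bbb,pgp_sub,pgp_inh
DB08149,,-8.81,1.00,0.11,0.45
DB07606,,-8.73,0.89,0.02,0.03
DB07227,L-778123,-8.72,0.98,0.03,0.34
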