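compound,assay,papp_ab,papp_ba,pct_recovery_ab,pct_recovery_ba,t_half_min,microsome_conc_mg_ml
39,caco2,7.2,0.6,26,19,,
propranolol,caco2,32.2,32.6,74,96,,
labetalol,caco2,8.3,38.2,99,103,,
39,microsomes,,,,,9.5,0.1
terfenadine,microsomes,,,,,16.9,0.1
verapamil,microsomes,,,,,26.6,0.1
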