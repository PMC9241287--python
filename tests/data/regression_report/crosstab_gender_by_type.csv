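gender,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
female,10,31.3,5,45.5,14,31.1
male,22,68.8,6,54.5,31,68.9
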