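age_group,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
<=60,5,15.6,3,27.3,12,26.7
>60,27,84.4,8,72.7,33,73.3
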