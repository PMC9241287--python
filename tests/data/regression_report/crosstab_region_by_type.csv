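region,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
rural,7,21.9,2,18.2,14,31.1
urban,25,78.1,9,81.8,31,68.9
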