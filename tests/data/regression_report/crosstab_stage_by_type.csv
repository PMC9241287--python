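stage,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
distant_mets,13,40.6,7,63.6,23,51.1
lymph_node_mets,5,15.6,1,9.1,8,17.8
no_mets,14,43.8,3,27.3,14,31.1
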