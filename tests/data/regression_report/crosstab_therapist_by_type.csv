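therapist,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
hospital_inpatient,23,71.9,10,90.9,37,82.2
other_physician,9,28.1,1,9.1,8,17.8
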