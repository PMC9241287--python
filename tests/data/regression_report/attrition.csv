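step,n,pct
candidates,159,100.0
excluded_not_confirmed,0,0.0
excluded_prior_lc_diagnosis,0,0.0
excluded_insufficient_pre_observation,7,4.4
excluded_other_primary_tumor,48,30.2
excluded_insufficient_post_observation,16,10.1
included,88,55.3
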