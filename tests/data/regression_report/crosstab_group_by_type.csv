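first_line_label,NSCLC_n,NSCLC_pct,SCLC_n,SCLC_pct,unclassifiable_n,unclassifiable_pct
Chemotherapy,19,59.4,11,100.0,0,0.0
Immunotherapy,7,21.9,0,0.0,0,0.0
Inhibitors,3,9.4,0,0.0,0,0.0
Radiotherapy,2,6.3,0,0.0,4,8.9
Study,1,3.1,0,0.0,1,2.2
bronchoscopy_no_surgery_no_therapy,0,0.0,0,0.0,4,8.9
late_therapy,0,0.0,0,0.0,1,2.2
no_followup_diagnosis,0,0.0,0,0.0,5,11.1
none_of_the_above,0,0.0,0,0.0,10,22.2
not_observable_in_line,0,0.0,0,0.0,9,20.0
other_treatment,0,0.0,0,0.0,4,8.9
surgery_no_therapy,0,0.0,0,0.0,7,15.6
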