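system,code,is_prefix,label,treatment_group,cancer_type,role
OPS,5-32,1,SYNTHETIC placeholder: atypical/segmental lung resection family,none,none,surgery
OPS,5-33,1,SYNTHETIC placeholder: lobectomy and pneumonectomy family,none,none,surgery
OPS,5-34,1,SYNTHETIC placeholder: thoracic wall / pleura / mediastinum operations family,none,none,surgery
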