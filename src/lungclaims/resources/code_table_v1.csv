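system,code,is_prefix,label,treatment_group,cancer_type,role
ICD10GM,C33,1,Malignant neoplasm of trachea,none,none,lc_diagnosis
ICD10GM,C34,1,Malignant neoplasm of bronchus and lung,none,none,lc_diagnosis
ICD10GM,C77,1,Secondary and unspecified malignant neoplasm of lymph nodes,none,none,lymph_met
ICD10GM,C78,1,Secondary malignant neoplasm of respiratory and digestive organs,none,none,distant_met
ICD10GM,C79,1,Secondary malignant neoplasm of other and unspecified sites,none,none,distant_met
ATC,L01XC06,0,Cetuximab,Immunotherapy,NSCLC,therapy
OPS,6-001A,0,Cetuximab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC07,0,Bevacizumab,Immunotherapy,NSCLC,therapy
OPS,6-0029,0,Bevacizumab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC11,0,Ipilimumab,Immunotherapy,NSCLC,therapy
OPS,6-006H,0,Ipilimumab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC17,0,Nivolumab,Immunotherapy,NSCLC,therapy
OPS,6-008M,0,Nivolumab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC18,0,Pembrolizumab,Immunotherapy,NSCLC,therapy
OPS,6-0093,0,Pembrolizumab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC22,0,Necitumumab,Immunotherapy,NSCLC,therapy
OPS,6-009G,0,Necitumumab (application),Immunotherapy,NSCLC,therapy
ATC,L01XC28,0,Durvalumab,Immunotherapy,NSCLC,therapy
ATC,L01XC31,0,Avelumab,Immunotherapy,NSCLC,therapy
ATC,L01XC32,0,Atezolizumab,Immunotherapy,NSCLC,therapy
OPS,8-547,1,Other immunotherapies,Immunotherapy,none,therapy
ATC,L01XE02,0,Gefitinib,Inhibitors,NSCLC,therapy
ATC,L01XE03,0,Erlotinib,Inhibitors,NSCLC,therapy
ATC,L01XE13,0,Afatinib,Inhibitors,NSCLC,therapy
ATC,L01XE16,0,Crizotinib,Inhibitors,NSCLC,therapy
OPS,6-006C,0,Crizotinib (application),Inhibitors,NSCLC,therapy
ATC,L01XE23,0,Dabrafenib,Inhibitors,NSCLC,therapy
OPS,6-0075,0,Dabrafenib (application),Inhibitors,NSCLC,therapy
ATC,L01XE25,0,Trametinib,Inhibitors,NSCLC,therapy
OPS,6-0097,0,Trametinib (application),Inhibitors,NSCLC,therapy
ATC,L01XE28,0,Ceritinib,Inhibitors,NSCLC,therapy
OPS,6-008A,0,Ceritinib (application),Inhibitors,NSCLC,therapy
ATC,L01XE31,0,Nintedanib,Inhibitors,NSCLC,therapy
ATC,L01XE35,0,Osimertinib,Inhibitors,NSCLC,therapy
ATC,L01AA01,0,Cyclophosphamide,Chemotherapy,SCLC,therapy
ATC,L01AA06,0,Ifosfamide,Chemotherapy,SCLC,therapy
ATC,L01AA07,0,Trofosfamide,Chemotherapy,SCLC,therapy
ATC,L01AD02,0,Lomustine,Chemotherapy,SCLC,therapy
ATC,L01AX03,0,Temozolomide,Chemotherapy,none,therapy
OPS,6-002E,0,Temozolomide (application),Chemotherapy,none,therapy
OPS,6-005C,0,Temozolomide (application),Chemotherapy,none,therapy
ATC,L01BA04,0,Pemetrexed,Chemotherapy,NSCLC,therapy
OPS,6-001C,0,Pemetrexed (application),Chemotherapy,NSCLC,therapy
ATC,L01BC02,0,5-Fluorouracil,Chemotherapy,NSCLC,therapy
ATC,L01BC05,0,Gemcitabine,Chemotherapy,NSCLC,therapy
OPS,6-0011,0,Gemcitabine (application),Chemotherapy,NSCLC,therapy
ATC,L01BC06,0,Capecitabine,Chemotherapy,none,therapy
ATC,L01CA04,0,Vinorelbine,Chemotherapy,NSCLC,therapy
ATC,L01CB01,0,Etoposide,Chemotherapy,SCLC,therapy
ATC,L01CD01,0,Paclitaxel / nab-paclitaxel,Chemotherapy,NSCLC,therapy
OPS,6-005D,0,Nab-paclitaxel (application),Chemotherapy,NSCLC,therapy
OPS,6-001F,0,Paclitaxel (application),Chemotherapy,NSCLC,therapy
ATC,L01CD02,0,Docetaxel,Chemotherapy,none,therapy
OPS,6-002H,0,Docetaxel (application),Chemotherapy,none,therapy
ATC,L01DB01,0,Doxorubicin,Chemotherapy,SCLC,therapy
OPS,6-001B,0,Doxorubicin (application),Chemotherapy,SCLC,therapy
OPS,6-0028,0,Doxorubicin (application),Chemotherapy,SCLC,therapy
ATC,L01DB03,0,Epirubicin,Chemotherapy,SCLC,therapy
ATC,L01DC03,0,Mitomycin,Chemotherapy,NSCLC,therapy
ATC,L01XA01,0,Cisplatin,Chemotherapy,none,therapy
ATC,L01XA02,0,Carboplatin,Chemotherapy,SCLC,therapy
ATC,L01XA03,0,Oxaliplatin,Chemotherapy,none,therapy
ATC,L01XX17,0,Topotecan,Chemotherapy,SCLC,therapy
OPS,6-0024,0,Topotecan (application),Chemotherapy,SCLC,therapy
ATC,L01XX19,0,Irinotecan / liposomal irinotecan,Chemotherapy,SCLC,therapy
OPS,6-0013,0,Irinotecan (application),Chemotherapy,SCLC,therapy
OPS,6-009E,0,Liposomal irinotecan (application),Chemotherapy,SCLC,therapy
ATC,V03AF03,0,Folinic acid,Chemotherapy,NSCLC,therapy
OPS,8-542,1,Non-complex chemotherapy,Chemotherapy,none,therapy
OPS,8-543,1,Moderately complex and intensive chemotherapy cycle,Chemotherapy,none,therapy
OPS,8-544,1,Highly complex and intensive chemotherapy cycle,Chemotherapy,none,therapy
OPS,8-546,1,Hyperthermic chemotherapy,Chemotherapy,none,therapy
OPS,8-549,1,Percutaneous closed organ perfusion with chemotherapeutic agents,Chemotherapy,none,therapy
OPS,8-52,1,Inpatient radiotherapy,Radiotherapy,none,therapy
EBM,25320,0,High-voltage therapy,Radiotherapy,none,therapy
EBM,25321,0,High-voltage therapy,Radiotherapy,none,therapy
EBM,25322,0,High-voltage therapy,Radiotherapy,none,therapy
EBM,25323,0,High-voltage therapy,Radiotherapy,none,therapy
EBM,25331,0,Brachytherapy,Radiotherapy,none,therapy
EBM,25333,0,Brachytherapy,Radiotherapy,none,therapy
EBM,25340,0,Radiotherapy planning,Radiotherapy,none,therapy
EBM,25341,0,Radiotherapy planning,Radiotherapy,none,therapy
EBM,25342,0,Radiotherapy planning,Radiotherapy,none,therapy
EBM,13461,0,Study participation (primary),Study,none,therapy
EBM,13492,0,Study participation (primary),Study,none,therapy
EBM,13494,0,Study participation (companion service),Study,none,study_marker
EBM,02100,0,Infusion at least 10 min (companion service),Study,none,study_marker
EBM,02101,0,Infusion at least 60 min (companion service),Study,none,study_marker
EBM,01510,0,Observation and care 2 h (companion service),Study,none,study_marker
EBM,01511,0,Observation and care 4 h (companion service),Study,none,study_marker
EBM,01512,0,Observation and care 6 h (companion service),Study,none,study_marker
OPS,8-541,1,Instillation and other application of drugs (inpatient treatment marker),none,none,inpatient_chemo_marker
EBM,19320,0,Biomarker testing,none,none,biomarker
EBM,19321,0,Biomarker testing,none,none,biomarker
EBM,19322,0,Biomarker testing,none,none,biomarker
OPS,1-991,1,Biomarker testing key,none,none,biomarker
OPS,1-992,1,Biomarker testing key,none,none,biomarker
OPS,1-6900,0,Diagnostic bronchoscopy,none,none,bronchoscopy
OPS,1-6901,0,Diagnostic bronchoscopy,none,none,bronchoscopy
OPS,1-620,1,Diagnostic tracheobronchoscopy,none,none,bronchoscopy
EBM,09315,0,Bronchoscopy,none,none,bronchoscopy
EBM,13662,0,Bronchoscopy,none,none,bronchoscopy
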