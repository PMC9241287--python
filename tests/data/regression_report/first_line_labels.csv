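patient_id,first_line_label
P000003,surgery_no_therapy
P000006,surgery_no_therapy
P000010,Chemotherapy
P000012,Immunotherapy
P000014,not_observable_in_line
P000017,Chemotherapy
P000018,Study
P000019,none_of_the_above
P000021,Chemotherapy
P000022,Inhibitors
P000032,Chemotherapy
P000033,not_observable_in_line
P000035,Chemotherapy
P000036,Chemotherapy
P000043,Chemotherapy
P000048,Chemotherapy
P000049,Study
P000054,not_observable_in_line
P000057,none_of_the_above
P000062,Chemotherapy
P000065,Chemotherapy
P000066,Immunotherapy
P000069,Radiotherapy
P000072,Chemotherapy
P000073,surgery_no_therapy
P000074,Radiotherapy
P000075,bronchoscopy_no_surgery_no_therapy
P000089,none_of_the_above
P000093,none_of_the_above
P000103,Immunotherapy
P000105,none_of_the_above
P000107,Chemotherapy
P000114,Chemotherapy
P000118,no_followup_diagnosis
P000119,other_treatment
P000130,Immunotherapy
P000131,none_of_the_above
P000133,surgery_no_therapy
P000134,not_observable_in_line
P000136,Chemotherapy
P000138,bronchoscopy_no_surgery_no_therapy
P000139,Chemotherapy
P000149,Chemotherapy
P000157,no_followup_diagnosis
P000159,no_followup_diagnosis
P000166,Radiotherapy
P000169,Chemotherapy
P000171,Immunotherapy
P000176,other_treatment
P000178,surgery_no_therapy
P000183,Chemotherapy
P000184,other_treatment
P000186,none_of_the_above
P000193,none_of_the_above
P000196,Radiotherapy
P000203,Chemotherapy
P000206,not_observable_in_line
P000208,Immunotherapy
P000211,no_followup_diagnosis
P000212,none_of_the_above
P000218,Chemotherapy
P000219,Inhibitors
P000224,not_observable_in_line
P000229,Radiotherapy
P000231,surgery_no_therapy
P000233,other_treatment
P000234,Chemotherapy
P000238,bronchoscopy_no_surgery_no_therapy
P000239,not_observable_in_line
P000241,Radiotherapy
P000244,Inhibitors
P000245,Chemotherapy
P000248,Chemotherapy
P000259,Chemotherapy
P000260,no_followup_diagnosis
P000262,none_of_the_above
P000264,bronchoscopy_no_surgery_no_therapy
P000266,not_observable_in_line
P000267,late_therapy
P000272,Chemotherapy
P000273,Chemotherapy
P000278,Chemotherapy
P000279,Chemotherapy
P000282,surgery_no_therapy
P000290,Chemotherapy
P000293,Immunotherapy
P000296,not_observable_in_line
P000297,Chemotherapy
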