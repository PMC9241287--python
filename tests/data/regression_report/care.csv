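patient_id,context,therapist,specialty,biomarker_setting,bronchoscopy_setting,surgery_flag
P000003,first,other_physician,internist,none,none,1
P000006,first,hospital_inpatient,,none,none,1
P000010,first,hospital_inpatient,,none,inpatient,0
P000012,first,other_physician,primary_care,none,outpatient,0
P000012,second,other_physician,primary_care,none,none,0
P000014,first,hospital_inpatient,,none,none,0
P000017,first,hospital_inpatient,,none,inpatient,0
P000017,second,hospital_inpatient,,none,inpatient,0
P000018,first,hospital_inpatient,,none,inpatient,0
P000019,first,other_physician,primary_care,none,none,0
P000021,first,other_physician,pulmonologist,outpatient,outpatient,0
P000021,second,other_physician,pulmonologist,none,none,0
P000022,first,hospital_inpatient,,none,none,0
P000032,first,hospital_inpatient,,inpatient,inpatient,0
P000033,first,hospital_inpatient,,none,none,0
P000035,first,hospital_inpatient,,none,none,0
P000035,second,other_physician,primary_care,none,none,0
P000036,first,hospital_inpatient,,none,inpatient,0
P000043,first,other_physician,pulmonologist,none,outpatient,0
P000048,first,other_physician,pulmonologist,none,outpatient,0
P000049,first,hospital_inpatient,,none,inpatient,0
P000049,second,unknown,,none,none,0
P000054,first,hospital_inpatient,,none,none,0
P000057,first,other_physician,primary_care,none,none,0
P000062,first,hospital_inpatient,,none,inpatient,0
P000065,first,hospital_inpatient,,none,inpatient,0
P000065,second,unknown,,none,none,0
P000066,first,other_physician,primary_care,none,outpatient,0
P000066,second,other_physician,primary_care,none,none,0
P000069,first,hospital_inpatient,,none,inpatient,0
P000069,second,other_physician,pulmonologist,none,none,0
P000072,first,hospital_inpatient,,none,inpatient,0
P000072,second,unknown,,none,none,0
P000073,first,hospital_inpatient,,none,none,1
P000074,first,hospital_inpatient,,none,none,0
P000075,first,hospital_inpatient,,none,outpatient,0
P000089,first,hospital_inpatient,,none,none,0
P000093,first,hospital_inpatient,,none,none,0
P000103,first,hospital_inpatient,,inpatient,inpatient,0
P000105,first,hospital_inpatient,,none,none,0
P000107,first,hospital_inpatient,,none,none,0
P000107,second,hospital_inpatient,,none,none,0
P000114,first,hospital_inpatient,,none,inpatient,0
P000114,second,other_physician,pulmonologist,none,none,0
P000118,first,hospital_inpatient,,none,none,0
P000119,first,hospital_inpatient,,none,none,0
P000130,first,other_physician,primary_care,none,none,0
P000130,second,other_physician,primary_care,none,none,0
P000131,first,hospital_inpatient,,none,none,0
P000133,first,hospital_inpatient,,none,none,1
P000134,first,hospital_inpatient,,none,none,0
P000136,first,hospital_inpatient,,none,none,0
P000138,first,other_physician,internist,none,outpatient,0
P000139,first,hospital_inpatient,,none,inpatient,0
P000149,first,hospital_inpatient,,inpatient,inpatient,0
P000157,first,hospital_inpatient,,none,none,0
P000159,first,hospital_inpatient,,none,none,0
P000166,first,hospital_inpatient,,none,inpatient,0
P000169,first,hospital_inpatient,,inpatient,inpatient,0
P000171,first,hospital_inpatient,,none,inpatient,0
P000176,first,other_physician,primary_care,none,none,0
P000178,first,hospital_inpatient,,none,none,1
P000183,first,other_physician,pulmonologist,none,outpatient,0
P000184,first,hospital_inpatient,,none,none,0
P000186,first,other_physician,internist,none,none,0
P000193,first,hospital_inpatient,,none,none,0
P000196,first,hospital_inpatient,,inpatient,inpatient,0
P000196,second,other_physician,primary_care,none,none,0
P000203,first,hospital_inpatient,,none,inpatient,0
P000206,first,hospital_inpatient,,none,none,0
P000208,first,hospital_inpatient,,none,inpatient,0
P000208,second,other_physician,primary_care,none,none,0
P000211,first,hospital_inpatient,,none,none,0
P000212,first,hospital_inpatient,,none,none,0
P000218,first,hospital_inpatient,,none,inpatient,0
P000219,first,hospital_inpatient,,none,inpatient,0
P000224,first,hospital_inpatient,,none,none,0
P000229,first,hospital_inpatient,,none,inpatient,0
P000229,second,other_physician,internist,none,inpatient,0
P000231,first,hospital_inpatient,,none,none,1
P000233,first,hospital_inpatient,,none,none,0
P000234,first,hospital_inpatient,,none,inpatient,0
P000234,second,other_physician,primary_care,none,none,0
P000238,first,other_physician,primary_care,none,outpatient,0
P000239,first,hospital_inpatient,,none,none,0
P000241,first,hospital_inpatient,,none,inpatient,0
P000244,first,other_physician,internist,none,outpatient,0
P000245,first,hospital_inpatient,,none,inpatient,0
P000248,first,other_physician,pulmonologist,none,outpatient,0
P000248,second,other_physician,pulmonologist,none,none,0
P000259,first,hospital_inpatient,,none,none,0
P000260,first,hospital_inpatient,,none,none,0
P000262,first,other_physician,pulmonologist,none,none,0
P000264,first,hospital_inpatient,,none,inpatient,0
P000266,first,hospital_inpatient,,none,none,0
P000267,first,hospital_inpatient,,none,none,0
P000272,first,hospital_inpatient,,none,inpatient,0
P000272,second,hospital_inpatient,,none,inpatient,0
P000273,first,hospital_inpatient,,none,none,0
P000278,first,hospital_inpatient,,none,inpatient,0
P000278,second,unknown,,none,none,0
P000279,first,hospital_inpatient,,none,inpatient,0
P000279,second,unknown,,none,none,0
P000282,first,hospital_inpatient,,none,none,1
P000290,first,other_physician,internist,none,outpatient,0
P000290,second,unknown,,none,none,0
P000293,first,hospital_inpatient,,none,inpatient,0
P000296,first,hospital_inpatient,,none,none,0
P000297,first,hospital_inpatient,,none,inpatient,0
P000297,second,other_physician,pulmonologist,none,none,0
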