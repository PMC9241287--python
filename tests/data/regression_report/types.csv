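patient_id,call,basis,conflicting
P000003,unclassifiable,none,0
P000006,unclassifiable,none,0
P000010,NSCLC,first_line,0
P000012,NSCLC,first_line,0
P000014,unclassifiable,none,0
P000017,SCLC,first_line,0
P000018,unclassifiable,none,0
P000019,unclassifiable,none,0
P000021,NSCLC,first_line,0
P000022,NSCLC,first_line,0
P000032,SCLC,first_line,0
P000033,unclassifiable,none,0
P000035,SCLC,first_line,0
P000036,SCLC,first_line,0
P000043,NSCLC,first_line,0
P000048,NSCLC,first_line,0
P000049,NSCLC,second_line,0
P000054,unclassifiable,none,0
P000057,unclassifiable,none,0
P000062,NSCLC,first_line,0
P000065,NSCLC,first_line,0
P000066,NSCLC,first_line,0
P000069,NSCLC,second_line,0
P000072,NSCLC,first_line,0
P000073,unclassifiable,none,0
P000074,unclassifiable,none,0
P000075,unclassifiable,none,0
P000089,unclassifiable,none,0
P000093,unclassifiable,none,0
P000103,NSCLC,first_line,0
P000105,unclassifiable,none,0
P000107,SCLC,first_line,0
P000114,SCLC,first_line,0
P000118,unclassifiable,none,0
P000119,unclassifiable,none,0
P000130,NSCLC,first_line,0
P000131,unclassifiable,none,0
P000133,unclassifiable,none,0
P000134,unclassifiable,none,0
P000136,NSCLC,first_line,0
P000138,unclassifiable,none,0
P000139,NSCLC,first_line,0
P000149,SCLC,first_line,0
P000157,unclassifiable,none,0
P000159,unclassifiable,none,0
P000166,unclassifiable,none,0
P000169,SCLC,first_line,0
P000171,NSCLC,first_line,0
P000176,unclassifiable,none,0
P000178,unclassifiable,none,0
P000183,SCLC,first_line,0
P000184,unclassifiable,none,0
P000186,unclassifiable,none,0
P000193,unclassifiable,none,0
P000196,unclassifiable,none,0
P000203,NSCLC,first_line,0
P000206,unclassifiable,none,0
P000208,NSCLC,first_line,0
P000211,unclassifiable,none,0
P000212,unclassifiable,none,0
P000218,NSCLC,first_line,0
P000219,NSCLC,first_line,0
P000224,unclassifiable,none,0
P000229,NSCLC,second_line,0
P000231,unclassifiable,none,0
P000233,unclassifiable,none,0
P000234,NSCLC,first_line,0
P000238,unclassifiable,none,0
P000239,unclassifiable,none,0
P000241,unclassifiable,none,0
P000244,NSCLC,first_line,0
P000245,NSCLC,first_line,0
P000248,NSCLC,first_line,0
P000259,SCLC,first_line,0
P000260,unclassifiable,none,0
P000262,unclassifiable,none,0
P000264,unclassifiable,none,0
P000266,unclassifiable,none,0
P000267,unclassifiable,none,0
P000272,NSCLC,first_line,0
P000273,SCLC,first_line,0
P000278,NSCLC,first_line,0
P000279,NSCLC,first_line,0
P000282,unclassifiable,none,0
P000290,NSCLC,first_line,0
P000293,NSCLC,first_line,0
P000296,unclassifiable,none,0
P000297,NSCLC,first_line,0
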