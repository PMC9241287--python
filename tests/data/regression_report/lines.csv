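patient_id,line,start,window_end,group
P000010,first,2016-04-22,2016-05-22,Chemotherapy
P000012,first,2016-04-10,2016-05-10,Immunotherapy
P000012,second,2016-05-16,2016-06-15,Chemotherapy
P000017,first,2015-07-07,2015-08-06,Chemotherapy
P000017,second,2015-08-31,2015-09-30,Chemotherapy
P000018,first,2015-11-12,2015-12-12,Study
P000021,first,2015-07-25,2015-08-24,Chemotherapy
P000021,second,2015-09-08,2015-10-08,Chemotherapy
P000022,first,2016-05-10,2016-06-09,Inhibitors
P000032,first,2015-05-10,2015-06-09,Chemotherapy
P000035,first,2015-06-14,2015-07-14,Chemotherapy
P000035,second,2015-09-02,2015-10-02,Chemotherapy
P000036,first,2016-10-25,2016-11-24,Chemotherapy
P000043,first,2016-06-04,2016-07-04,Chemotherapy
P000048,first,2016-03-28,2016-04-27,Chemotherapy
P000049,first,2016-04-14,2016-05-14,Study
P000049,second,2016-06-22,2016-07-22,Chemotherapy
P000062,first,2015-07-01,2015-07-31,Chemotherapy
P000065,first,2016-04-05,2016-05-05,Chemotherapy
P000065,second,2016-06-17,2016-07-17,Chemotherapy
P000066,first,2016-02-21,2016-03-22,Immunotherapy
P000066,second,2016-05-20,2016-06-19,Radiotherapy
P000069,first,2015-09-10,2015-10-10,Radiotherapy
P000069,second,2015-12-01,2015-12-31,Chemotherapy
P000072,first,2015-04-19,2015-05-19,Chemotherapy
P000072,second,2015-07-07,2015-08-06,Chemotherapy
P000074,first,2016-04-03,2016-05-03,Radiotherapy
P000103,first,2015-07-26,2015-08-25,Immunotherapy
P000107,first,2015-11-06,2015-12-06,Chemotherapy
P000107,second,2015-12-24,2016-01-23,Chemotherapy
P000114,first,2015-08-02,2015-09-01,Chemotherapy
P000114,second,2015-10-29,2015-11-28,Immunotherapy
P000130,first,2016-12-15,2017-01-14,Immunotherapy
P000130,second,2017-03-07,2017-04-06,Chemotherapy
P000136,first,2015-09-25,2015-10-25,Chemotherapy
P000139,first,2017-02-23,2017-03-25,Chemotherapy
P000149,first,2016-05-22,2016-06-21,Chemotherapy
P000166,first,2015-04-28,2015-05-28,Radiotherapy
P000169,first,2016-05-30,2016-06-29,Chemotherapy
P000171,first,2016-02-15,2016-03-16,Immunotherapy
P000183,first,2017-03-25,2017-04-24,Chemotherapy
P000196,first,2017-03-14,2017-04-13,Radiotherapy
P000196,second,2017-04-20,2017-05-20,Radiotherapy
P000203,first,2015-04-30,2015-05-30,Chemotherapy
P000208,first,2015-09-04,2015-10-04,Immunotherapy
P000208,second,2015-11-08,2015-12-08,Chemotherapy
P000218,first,2015-05-16,2015-06-15,Chemotherapy
P000219,first,2016-11-18,2016-12-18,Inhibitors
P000229,first,2015-01-17,2015-02-16,Radiotherapy
P000229,second,2015-04-17,2015-05-17,Chemotherapy
P000234,first,2015-06-17,2015-07-17,Chemotherapy
P000234,second,2015-09-07,2015-10-07,Chemotherapy
P000241,first,2015-07-06,2015-08-05,Radiotherapy
P000244,first,2015-05-05,2015-06-04,Inhibitors
P000245,first,2016-08-27,2016-09-26,Chemotherapy
P000248,first,2017-03-01,2017-03-31,Chemotherapy
P000248,second,2017-04-19,2017-05-19,Chemotherapy
P000259,first,2016-07-24,2016-08-23,Chemotherapy
P000272,first,2015-10-17,2015-11-16,Chemotherapy
P000272,second,2015-11-23,2015-12-23,Chemotherapy
P000273,first,2016-10-27,2016-11-26,Chemotherapy
P000278,first,2015-09-16,2015-10-16,Chemotherapy
P000278,second,2015-12-11,2016-01-10,Chemotherapy
P000279,first,2016-06-13,2016-07-13,Chemotherapy
P000279,second,2016-07-30,2016-08-29,Chemotherapy
P000290,first,2016-03-30,2016-04-29,Chemotherapy
P000290,second,2016-06-12,2016-07-12,Chemotherapy
P000293,first,2015-05-31,2015-06-30,Immunotherapy
P000297,first,2015-12-18,2016-01-17,Chemotherapy
P000297,second,2016-03-17,2016-04-16,Chemotherapy
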