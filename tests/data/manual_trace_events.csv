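patient_id,date,channel,code,flag
P1,2010-01-01,diagnosis,F43.10,
P1,2010-03-01,diagnosis,E11.9,
P1,2010-06-01,diagnosis,E11.9,
P1,2010-07-15,diagnosis,F10.20,
P2,2010-01-01,diagnosis,F43.10,
P2,2010-03-01,medication,RX0001,
P2,2010-06-01,diagnosis,J45.909,
P2,2010-11-01,diagnosis,F10.20,
P3,2010-01-01,diagnosis,F43.10,
P3,2010-01-01,diagnosis,F10.20,
P3,2010-02-01,diagnosis,E11.9,
P4,2009-06-01,diagnosis,F10.20,
P4,2010-01-01,diagnosis,F43.10,
P4,2010-03-01,diagnosis,E11.9,
P5,2009-12-01,diagnosis,E11.9,
P5,2010-01-01,diagnosis,F43.10,
P6,2010-01-01,diagnosis,F43.10,
P6,2010-04-01,lab,LAB001,HIGH
P6,2010-06-30,diagnosis,F10.20,
P7,2010-01-01,diagnosis,F43.10,
P7,2010-02-01,diagnosis,M54.5,
P7,2010-05-01,diagnosis,M54.5,
P8,2010-01-01,diagnosis,F43.10,
P8,2010-03-15,diagnosis,E11.9,
P8,2011-08-01,diagnosis,E11.9,
P8,2011-09-01,diagnosis,F10.20,
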