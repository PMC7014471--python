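compound	schedule	ic50_uM	cl_lo_uM	cl_hi_uM
doxorubicin	24h	14.4	12.8	16.2
doxorubicin	48h	3.6	2.6	5.2
doxorubicin	72h	1.6	1.4	1.8
doxorubicin	2h	13.6	2.6	20.2
doxorubicin	2hx2	11.6	6.4	20.4
doxorubicin	2hx3	5.8	2.8	11.6
beta_caryophyllene	24h	197.0	127.0	314.5
beta_caryophyllene	48h	121.0	94.0	159.5
beta_caryophyllene	72h	113.0	88.5	144.0
beta_caryophyllene	2h	379.5	171.5	460.5
beta_caryophyllene	2hx2	265.5	110.5	327.0
beta_caryophyllene	2hx3	251.0	71.5	372.0
beta_caryophyllene_oxide	24h	195.0	172.5	219.5
beta_caryophyllene_oxide	48h	162.0	146.0	180.0
beta_caryophyllene_oxide	72h	152.5	136.5	170.0
beta_caryophyllene_oxide	2h	354.5	190.5	441.0
beta_caryophyllene_oxide	2hx2	281.0	157.5	360.5
beta_caryophyllene_oxide	2hx3	256.5	123.5	334.0
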