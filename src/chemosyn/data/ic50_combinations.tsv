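drug	modulator	modulator_conc_uM	schedule	ic50_uM	cl_lo_uM	cl_hi_uM	rr
doxorubicin	beta_caryophyllene	50	24h	8.6	7.6	13.8	1.7
doxorubicin	beta_caryophyllene	100	24h	1.0	0.4	1.8	14.4
doxorubicin	beta_caryophyllene_oxide	50	24h	5.0	4.2	5.8	2.9
doxorubicin	beta_caryophyllene_oxide	100	24h	3.4	2.2	4.6	4.2
doxorubicin	beta_caryophyllene	50	48h	3.2	2.0	5.2	1.4
doxorubicin	beta_caryophyllene	100	48h	2.8	1.2	5.2	1.7
doxorubicin	beta_caryophyllene_oxide	50	48h	3.2	1.6	5.2	1.6
doxorubicin	beta_caryophyllene_oxide	100	48h	2.8	1.2	4.8	1.8
doxorubicin	beta_caryophyllene	50	72h	1.0	0.8	1.4	1.6
doxorubicin	beta_caryophyllene	100	72h	1.2	0.6	3.4	1.3
doxorubicin	beta_caryophyllene_oxide	50	72h	1.0	0.8	1.6	1.6
doxorubicin	beta_caryophyllene_oxide	100	72h	1.2	0.6	2.6	1.3
doxorubicin	beta_caryophyllene	50	2h	8.2	3.2	21.4	1.7
doxorubicin	beta_caryophyllene	100	2h	3.6	1.8	7.2	3.8
doxorubicin	beta_caryophyllene_oxide	50	2h	6.6	2.4	18.0	2.1
doxorubicin	beta_caryophyllene_oxide	100	2h	8.6	5.0	14.0	1.6
doxorubicin	beta_caryophyllene	50	2hx2	3.2	1.4	7.0	2.6
doxorubicin	beta_caryophyllene	100	2hx2	4.6	2.2	9.6	1.8
doxorubicin	beta_caryophyllene_oxide	50	2hx2	2.2	0.2	8.4	3.7
doxorubicin	beta_caryophyllene_oxide	100	2hx2	5.6	2.6	12.2	1.5
doxorubicin	beta_caryophyllene	50	2hx3	3.2	1.8	5.4	1.8
doxorubicin	beta_caryophyllene	100	2hx3	3.4	2.0	6.6	1.7
doxorubicin	beta_caryophyllene_oxide	50	2hx3	4.6	3.0	6.2	1.3
doxorubicin	beta_caryophyllene_oxide	100	2hx3	5.4	3.6	9.0	1.1
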