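drug	modulator	modulator_conc_uM	schedule	ci
doxorubicin	beta_caryophyllene	50	24h	0.85
doxorubicin	beta_caryophyllene	100	24h	0.58
doxorubicin	beta_caryophyllene_oxide	50	24h	0.61
doxorubicin	beta_caryophyllene_oxide	100	24h	0.75
doxorubicin	beta_caryophyllene	50	2h	0.73
doxorubicin	beta_caryophyllene	100	2h	0.52
doxorubicin	beta_caryophyllene_oxide	50	2h	0.62
doxorubicin	beta_caryophyllene_oxide	100	2h	0.91
doxorubicin	beta_caryophyllene	50	2hx2	0.58
doxorubicin	beta_caryophyllene	100	2hx2	0.94
doxorubicin	beta_caryophyllene_oxide	50	2hx2	0.44
doxorubicin	beta_caryophyllene_oxide	100	2hx2	1.02
doxorubicin	beta_caryophyllene	50	2hx3	0.75
doxorubicin	beta_caryophyllene	100	2hx3	0.99
doxorubicin	beta_caryophyllene_oxide	50	2hx3	0.99
doxorubicin	beta_caryophyllene_oxide	100	2hx3	1.3
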