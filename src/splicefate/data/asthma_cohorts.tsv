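cohort	scale	estimate	ci_low	ci_high	n_cases	n_controls
Iceland	log_odds	0.36	0.21	0.61	3512	298026
Netherlands	log_odds	1.08	0.36	3.21	351	2830
Germany	log_odds	0.89	0.14	5.48	284	252
Denmark-1	log_odds	0.72	0.29	1.79	1121	1004
Denmark-2	log_odds	0.24	0.06	0.94	1197	865
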