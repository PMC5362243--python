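cohort	scale	estimate	ci_low	ci_high	n
Iceland	sd_units	-0.21	-0.27	-0.16	103104
Netherlands	sd_units	-0.48	-0.93	-0.03	1370
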