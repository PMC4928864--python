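# Published serum microRNA associations with FEV1% predicted (transcribed report table).
feature_id	lit_flag	fetal	target_genes	beta	ci_low	ci_high	p_value
hsa-miR-142-3p	none	0	CCNT2,LRRC32	2.03	0.40	3.66	0.015
hsa-miR-27b-3p	Y	0	MMP13,PAX3,PSAP	-2.68	-5.19	-0.18	0.036
hsa-miR-374a-5p	Y	0	CEBPB	1.60	0.17	3.03	0.028
hsa-miR-454-3p	Y2	0		1.37	0.02	2.72	0.046
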