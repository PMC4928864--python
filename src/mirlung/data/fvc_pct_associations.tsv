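# Published serum microRNA associations with FVC% predicted (transcribed report table).
feature_id	lit_flag	fetal	target_genes	beta	ci_low	ci_high	p_value
hsa-miR-106b-5p	Y	0	TWIST1	-2.16	-4.02	-0.29	0.024
hsa-miR-15b-5p	Y	0		-2.76	-5.34	-0.18	0.037
hsa-miR-223-5p	Y	0		-2.11	-4.21	-0.02	0.048
hsa-miR-320a	Y2	1		3.30	0.34	6.26	0.029
hsa-miR-339-3p	Y	0		-1.66	-3.21	-0.11	0.036
hsa-miR-340-5p	Y	0		-1.62	-2.95	-0.28	0.018
hsa-miR-376c-3p	none	0		-1.56	-2.94	-0.18	0.027
hsa-miR-645	none	0		1.75	0.22	3.28	0.026
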