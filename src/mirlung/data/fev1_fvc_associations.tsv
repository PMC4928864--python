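# Published serum microRNA associations with FEV1/FVC (transcribed report table).
# lit_flag: Y = reported in >=1 prior asthma study, Y2 = in >=2; fetal = significant
# gestational-age association in fetal lung; target_genes = functionally validated
# targets with GWAS asthma/FEV1-change traits (comma-separated; empty if none).
feature_id	lit_flag	fetal	target_genes	beta	ci_low	ci_high	p_value
hsa-miR-126-3p	Y	1	CXCR4,PITPNC1	1.23	0.56	1.91	0.0004
hsa-miR-1290	Y	0		0.76	0.05	1.48	0.0372
hsa-miR-139-5p	none	0	CXCR4	1.48	0.22	2.74	0.022
hsa-miR-142-3p	none	0	CCNT2,LRRC32	1.00	0.06	1.95	0.0378
hsa-miR-146b-5p	none	0		1.07	0.16	1.98	0.0209
hsa-miR-15b-5p	Y	0		1.98	0.38	3.59	0.016
hsa-miR-16-5p	Y	0		0.78	0.09	1.47	0.0269
hsa-miR-186-5p	none	0		1.11	0.41	1.82	0.0022
hsa-miR-191-5p	none	0	CEBPB	1.10	0.43	1.76	0.0014
hsa-miR-203a-3p	Y2	1	ASAP1	0.76	0.01	1.52	0.0477
hsa-miR-206	none	0	GPD2,PAX3	-1.15	-2.12	-0.17	0.0213
hsa-miR-26a-5p	Y2	1		0.99	0.00	1.97	0.0497
hsa-miR-301a-3p	Y	0		0.87	0.02	1.73	0.0453
hsa-miR-30b-5p	Y2	1		1.30	0.07	2.54	0.0392
hsa-miR-331-3p	none	0	NRP2	1.69	0.31	3.06	0.0166
hsa-miR-342-3p	Y	1		0.85	0.19	1.5	0.012
hsa-miR-374a-5p	Y	0	CEBPB	1.14	0.31	1.97	0.0076
hsa-miR-409-3p	none	1		1.18	0.27	2.09	0.0113
hsa-miR-454-3p	Y2	0		1.13	0.34	1.92	0.0054
hsa-miR-484	none	0		1.54	0.13	2.96	0.0327
hsa-miR-660-5p	Y	0		1.61	0.21	3.01	0.0248
hsa-miR-942-5p	none	1		1.02	0.01	2.02	0.0472
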