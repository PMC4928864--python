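# Published sex-stratified significance calls for the 22 FEV1/FVC microRNAs
# (transcribed report table). fetal = significant gestational-age association.
feature_id	fetal	male_significant	male_p	female_significant	female_p
hsa-miR-126-3p	1	1	0.045	1	0.004
hsa-miR-1290	0	0	0.889	1	0.003
hsa-miR-139-5p	0	1	0.048	0	0.186
hsa-miR-142-3p	0	0	0.577	1	0.028
hsa-miR-146b-5p	0	0	0.114	0	0.095
hsa-miR-15b-5p	0	1	0.028	0	0.222
hsa-miR-16-5p	0	0	0.257	0	0.057
hsa-miR-186-5p	0	1	0.019	0	0.058
hsa-miR-191-5p	0	0	0.142	1	0.002
hsa-miR-203a-3p	1	0	0.338	0	0.066
hsa-miR-206	0	0	0.056	0	0.338
hsa-miR-26a-5p	1	0	0.138	0	0.207
hsa-miR-301a-3p	0	0	0.251	0	0.084
hsa-miR-30b-5p	1	0	0.258	0	0.087
hsa-miR-331-3p	0	0	0.134	0	0.067
hsa-miR-342-3p	1	1	0.044	0	0.132
hsa-miR-374a-5p	0	1	0.032	0	0.106
hsa-miR-409-3p	1	1	0.005	0	0.415
hsa-miR-454-3p	0	1	0.028	0	0.081
hsa-miR-484	0	0	0.143	0	0.132
hsa-miR-660-5p	0	1	0.032	0	0.339
hsa-miR-942-5p	1	1	0.041	0	0.465
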