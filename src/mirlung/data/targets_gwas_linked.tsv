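# Functionally validated miRTarBase target genes with GWAS asthma/lung-function
# traits, per microRNA (transcribed from the published association tables; the
# full target lists live in the study's supplement and are not carried here).
feature_id	gene
hsa-miR-126-3p	CXCR4
hsa-miR-126-3p	PITPNC1
hsa-miR-139-5p	CXCR4
hsa-miR-142-3p	CCNT2
hsa-miR-142-3p	LRRC32
hsa-miR-191-5p	CEBPB
hsa-miR-203a-3p	ASAP1
hsa-miR-206	GPD2
hsa-miR-206	PAX3
hsa-miR-27b-3p	MMP13
hsa-miR-27b-3p	PAX3
hsa-miR-27b-3p	PSAP
hsa-miR-331-3p	NRP2
hsa-miR-374a-5p	CEBPB
hsa-miR-106b-5p	TWIST1
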