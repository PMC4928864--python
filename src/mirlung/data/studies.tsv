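# The 15 prior asthma microRNA case-control studies used for literature flags
# (transcribed report table: first author, year, PubMed id, source tissue).
study_id	pubmed_id	source
Jardim2012	22679274	Bronchial epithelia
Levanen2013	23333113	Bronchoalveolar lavage fluid exosomes
Liu2012	22895815	Lymphocytes
Nakano2013	23954351	CD4+ T cells
NicodemusJohnson2013	23534973	Airway epithelia, white blood cells
Panganiban2012	23885321	Serum
Panganiban2016	27025347	Serum
Perry2014	23944957	Airway smooth muscles
Pinkerton2013	23628339	Exhaled breath condensate
Seumois2012	23304658	CD4+ T cells
Solberg2012	22955319	Airway epithelia
Suojalehto2014	24513959	Nasal mucosa
Tsitsiou2012	21917308	CD8+ T cells
Williams2009	19521514	Airway biopsies
Yamamoto2012	23170939	Peripheral blood mononuclear cells
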