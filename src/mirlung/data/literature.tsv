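# SYNTHETIC study->microRNA membership. The published report prints only the
# per-feature flags (Y = reported in >=1 of 15 prior asthma studies, Y2 = in
# >=2); the true per-study membership lists live in its supplement. This
# fixture assigns features to pseudo-arbitrary studies so that each feature's
# study COUNT reproduces its printed flag; the specific study assignments are
# not claims about the underlying studies.
study_id	feature_id
Jardim2012	hsa-miR-126-3p
Levanen2013	hsa-miR-1290
Liu2012	hsa-miR-15b-5p
Nakano2013	hsa-miR-16-5p
NicodemusJohnson2013	hsa-miR-301a-3p
Panganiban2012	hsa-miR-342-3p
Panganiban2016	hsa-miR-374a-5p
Perry2014	hsa-miR-660-5p
Pinkerton2013	hsa-miR-27b-3p
Seumois2012	hsa-miR-106b-5p
Solberg2012	hsa-miR-223-5p
Suojalehto2014	hsa-miR-339-3p
Tsitsiou2012	hsa-miR-340-5p
Williams2009	hsa-miR-203a-3p
Yamamoto2012	hsa-miR-203a-3p
Jardim2012	hsa-miR-26a-5p
Levanen2013	hsa-miR-26a-5p
Liu2012	hsa-miR-30b-5p
Nakano2013	hsa-miR-30b-5p
NicodemusJohnson2013	hsa-miR-454-3p
Panganiban2012	hsa-miR-454-3p
Panganiban2016	hsa-miR-320a
Perry2014	hsa-miR-320a
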