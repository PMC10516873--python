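id	name	stoichiometry	lower_bound	upper_bound	gene_associated	subsystem
EX_photon	Photon exchange	photon_c:-1	-45.0	0.0	0	Exchange
EX_co2	CO2 exchange	co2_c:-1	-10.0	1000.0	0	Exchange
EX_alkene	Alkene export	alkene_c:-1	0.0	1000.0	0	Exchange
EX_h2o	Water exchange	h2o_c:-1	-1000.0	1000.0	0	Exchange
EX_h	Proton exchange	h_c:-1	-1000.0	1000.0	0	Exchange
LEF	Linear electron flow (photosynthesis)	adp_c:-0.32;atp_c:0.32;nadp_c:-0.25;nadph_c:0.25;photon_c:-1;pi_c:-0.32	0.0	1000.0	1	Photosynthesis
CBB	Carbon fixation (CBB cycle lump)	adp_c:3;atp_c:-3;co2_c:-1;fixedc_c:1;nadp_c:2;nadph_c:-2;pi_c:3	0.0	1000.0	1	Calvin cycle
BIOMASS	Biomass pseudo-reaction	adp_c:1;atp_c:-1;fixedc_c:-1;pi_c:1	0.0	1000.0	0	Biomass
ALKSYN	Alkene synthesis	adp_c:2;alkene_c:1;atp_c:-2;fixedc_c:-1;nadp_c:1;nadph_c:-1;pi_c:2	0.0	1000.0	1	Heterologous alkene biosynthesis
FLV	Flavodiiron-like NADPH dissipation	nadp_c:1;nadph_c:-1	0.0	1000.0	1	Photosynthesis
ATPM	ATP maintenance requirement	adp_c:1;atp_c:-1;h2o_c:-1;h_c:1;pi_c:1	0.0	inf	0	Maintenance
CATN	Catabolic NAD reduction (carbon-wasting)	co2_c:1;fixedc_c:-1;nad_c:-1;nadh_c:1	0.0	1000.0	1	Catabolism
NDH	NADH dehydrogenase (dissipative)	nad_c:1;nadh_c:-1	0.0	1000.0	1	Oxidative Phosphorylation
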