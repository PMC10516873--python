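id	name	compartment	formula	charge
photon_c	Photon	c		0
co2_c	Carbon dioxide	c	CO2	0
fixedc_c	Fixed carbon (triose-equivalent, per C)	c	CH2O	0
alkene_c	Alkene product (per C)	c	CH2	0
atp_c	ATP	c		0
adp_c	ADP	c		0
pi_c	Orthophosphate	c		0
nadp_c	NADP+	c		0
nadph_c	NADPH	c		0
nad_c	NAD+	c		0
nadh_c	NADH	c		0
h2o_c	Water	c	H2O	0
h_c	Proton	c	H	1
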