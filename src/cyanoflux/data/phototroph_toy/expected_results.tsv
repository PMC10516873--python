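quantity	value	units	note
mu_max	3.6	1/h	biomass maximum; ATP-limited: 0.32*45/4
p_max	2.88	mmol/gDW/h	product maximum; ATP-limited: 0.32*45/5
two_step_product_at_0.10	2.592	mmol/gDW/h	0.9 * p_max on the linear frontier
atp_flux_sum_biomass	14.4	mmol/gDW/h	0.32 * 45, photon budget saturated
nadph_flux_sum_biomass	11.25	mmol/gDW/h	0.25 * 45
nadh_flux_sum_biomass	0.0	mmol/gDW/h	NAD(H) couple inactive at optimum
atp_nadph_ratio_biomass	1.28	dimensionless	equals the electron-chain output ratio
co2_uptake_biomass	3.6	mmol/gDW/h	one CO2 fixed per biomass unit
flv_flux_biomass	4.05	mmol/gDW/h	NADPH surplus through the dissipation valve
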