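# Ethylene biosynthesis through the ethylene-forming enzyme (EFE), which
# consumes 2-oxoglutarate and L-arginine; guanidine is drained by a demand
# pseudo-reaction.  The EFE stoichiometry is the published composite
# mechanism (3 AKG + 1 Arg per 2 ethylene) and is replaceable data.
name: ethylene
new_metabolites:
  - {id: ethylene_c, name: Ethylene, compartment: c, formula: C2H4, charge: 0}
  - {id: guanidine_c, name: Guanidine, compartment: c, formula: CH5N3, charge: 0}
reactions:
  - {id: EFE, name: Ethylene-forming enzyme,
     stoichiometry: "akg_c:-3;arg__L_c:-1;o2_c:-3;ethylene_c:2;succ_c:1;co2_c:7;guanidine_c:1;1pyr5c_c:1;h2o_c:3",
     lower_bound: 0, upper_bound: 1000, gene_associated: true,
     subsystem: Heterologous alkene biosynthesis}
  - {id: DM_guanidine_c, name: Guanidine drain,
     stoichiometry: "guanidine_c:-1",
     lower_bound: 0, upper_bound: 1000, gene_associated: false,
     subsystem: Heterologous alkene biosynthesis}
  - {id: DM_ethylene_c, name: Ethylene export,
     stoichiometry: "ethylene_c:-1",
     lower_bound: 0, upper_bound: 1000, gene_associated: false,
     subsystem: Heterologous alkene biosynthesis}
export_reaction_id: DM_ethylene_c
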