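# 1-undecene biosynthesis: oxidative decarboxylation of dodecanoate
# (laurate, C12 fatty acid) by the UndA-type nonheme oxidase.
name: undecene
new_metabolites:
  - {id: undecene_c, name: 1-undecene, compartment: c, formula: C11H22, charge: 0}
reactions:
  - {id: UNDA, name: Fatty acid decarboxylating oxidase (UndA),
     stoichiometry: "ddca_c:-1;o2_c:-1;h_c:-2;undecene_c:1;co2_c:1;h2o_c:2",
     lower_bound: 0, upper_bound: 1000, gene_associated: true,
     subsystem: Heterologous alkene biosynthesis}
  - {id: DM_undecene_c, name: 1-undecene export,
     stoichiometry: "undecene_c:-1",
     lower_bound: 0, upper_bound: 1000, gene_associated: false,
     subsystem: Heterologous alkene biosynthesis}
export_reaction_id: DM_undecene_c
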