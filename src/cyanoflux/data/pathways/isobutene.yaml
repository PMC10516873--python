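# Isobutene biosynthesis: oxidative decarboxylation of
# 4-methyl-2-oxopentanoate (ketoleucine, produced by the native
# branched-chain amino acid pathway through IPMD) to isobutene.
name: isobutene
new_metabolites:
  - {id: isobutene_c, name: Isobutene, compartment: c, formula: C4H8, charge: 0}
reactions:
  - {id: KICDC, name: Ketoisocaproate oxygenase/decarboxylase,
     stoichiometry: "4mop_c:-1;o2_c:-1;h_c:-1;isobutene_c:1;co2_c:2;h2o_c:1",
     lower_bound: 0, upper_bound: 1000, gene_associated: true,
     subsystem: Heterologous alkene biosynthesis}
  - {id: DM_isobutene_c, name: Isobutene export,
     stoichiometry: "isobutene_c:-1",
     lower_bound: 0, upper_bound: 1000, gene_associated: false,
     subsystem: Heterologous alkene biosynthesis}
export_reaction_id: DM_isobutene_c
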