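# Isoprene biosynthesis: a single isoprene synthase acting on the native
# MEP-pathway intermediate DMAPP, plus the cytoplasmic export
# pseudo-reaction that scenario layers set as objective.
name: isoprene
new_metabolites:
  - {id: isoprene_c, name: Isoprene, compartment: c, formula: C5H8, charge: 0}
reactions:
  - {id: ISPS, name: Isoprene synthase,
     stoichiometry: "dmpp_c:-1;isoprene_c:1;ppi_c:1",
     lower_bound: 0, upper_bound: 1000, gene_associated: true,
     subsystem: Heterologous alkene biosynthesis}
  - {id: DM_isoprene_c, name: Isoprene export,
     stoichiometry: "isoprene_c:-1",
     lower_bound: 0, upper_bound: 1000, gene_associated: false,
     subsystem: Heterologous alkene biosynthesis}
export_reaction_id: DM_isoprene_c
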