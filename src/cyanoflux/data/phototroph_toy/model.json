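{
  "model_id": "phototroph_toy",
  "biomass_reactions": ["BIOMASS"],
  "objective": {"BIOMASS": 1.0},
  "annotations": {
    "export_reaction": "EX_alkene",
    "description": "Frozen minimal phototroph: photon-limited linear electron flow at an ATP/NADPH output ratio of 1.28, lumped CBB carbon fixation, a biomass/product trade-off with distinct cofactor demands, dissipation valves and ATP maintenance. Closed-form optima are documented in cyanoflux.synthetic.PHOTOTROPH_CLOSED_FORMS."
  }
}
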