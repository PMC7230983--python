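{
  "provenance": "SYNTHETIC schematic DOPC/EggSM/Chol diagram shipped with vesifuse. Region boundaries are illustrative cholesterol-fraction cuts, not measured phase boundaries: gel/liquid coexistence below 15 mol% Chol, Lo/Ld coexistence between 15 and 50 mol% Chol, uniform liquid above 50 mol% Chol. Replace with an empirical diagram for quantitative work.",
  "regions": [
    {
      "label": "gel_liquid_coexistence",
      "vertices": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.85, 0.15], [0.85, 0.0, 0.15]]
    },
    {
      "label": "Lo_Ld_coexistence",
      "vertices": [[0.85, 0.0, 0.15], [0.0, 0.85, 0.15], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]]
    },
    {
      "label": "uniform_liquid",
      "vertices": [[0.5, 0.0, 0.5], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]]
    }
  ]
}
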