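{
  "label": "best_insilico_proprietary",
  "lipophilicity": {
    "sources": [
      {"source": "BayerLogD", "subtype": "LogD"},
      {"source": "BayerLogMA", "subtype": "LogMA"}
    ],
    "consensus": true,
    "conversion": null
  },
  "pka_source": "ChemAxon",
  "partitioning_method": "pksim",
  "fu_source": "ADMETLab",
  "clearance": {"source": "ADMETLab", "mode": "plasma"},
  "renal_passive": false,
  "solubility": {"source": "SimPlus", "subtype": "FaSSIF"},
  "permeability": {"source": "ADMETLab", "subtype": "MDCK", "scaling": "direct", "scaling_factor": null}
}
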