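{
  "label": "best_insilico_free",
  "lipophilicity": {
    "sources": [
      {"source": "ADMETLab", "subtype": "LogD"}
    ],
    "consensus": false,
    "conversion": null
  },
  "pka_source": null,
  "partitioning_method": "pksim",
  "fu_source": "ADMETLab",
  "clearance": {"source": "ADMETLab", "mode": "plasma"},
  "renal_passive": false,
  "solubility": {"source": "ADMETLab", "subtype": "aqueous"},
  "permeability": {"source": "ADMETLab", "subtype": "MDCK", "scaling": "direct", "scaling_factor": null}
}
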