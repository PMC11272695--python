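{
  "description": "Linear regressions mapping octanol-based lipophilicity onto membrane affinity (LogMA = slope * value + intercept). Coefficients are transcribed approximations of the cited empirical relationships and are configuration data: override with your own file if you have better fits.",
  "conversions": {
    "yun_edginton_logp_to_logma": {
      "input_subtype": "LogP",
      "slope": 0.81,
      "intercept": 0.29,
      "citation": "Yun & Edginton membrane-affinity regression (octanol LogP basis)"
    },
    "endo_logp_to_logma": {
      "input_subtype": "LogP",
      "slope": 1.01,
      "intercept": 0.71,
      "citation": "Endo liposome-water vs octanol-water correlation (neutral species)"
    },
    "loidl_stahlhofen_logd_to_logma": {
      "input_subtype": "LogD",
      "slope": 0.90,
      "intercept": 0.52,
      "citation": "Re-fit of published solid-supported-membrane affinity data (LogD basis)"
    }
  }
}
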