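{
  "description": "Surrogate coefficients for the engine's internal intestinal-permeability equation P = a * 10^(b*logMA) * MW^c [cm/min]. Configurable: re-fit against a fitted-permeability reference table when one is available.",
  "a": 0.0005,
  "b": 0.5,
  "c": -0.5
}
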