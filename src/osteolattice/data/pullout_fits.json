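{
  "label": "pullout-Fmax-vs-HU",
  "fits": {
    "linear": {"model": "linear", "constant": 5.65, "exponent": 3.56, "r_squared": 0.73, "p_value": 0.0},
    "power": {"model": "power", "constant": 2.77, "exponent": 1.04, "r_squared": 0.83, "p_value": 0.0},
    "exponential": {"model": "exponential", "constant": 177.75, "exponent": 0.01, "r_squared": 0.78, "p_value": 0.0}
  },
  "hu_range": [58, 343],
  "fmax_range_N": [183, 1567]
}
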