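{
  "label": "human-bone-vs-HU",
  "laws": {
    "E": {"constant": 0.094, "exponent": 1.25, "r_squared": 0.42, "p_max": 0.001},
    "sigma_y": {"constant": 0.001, "exponent": 1.34, "r_squared": 0.62, "p_max": 0.001},
    "sigma_p": {"constant": 0.0, "exponent": 1.54, "r_squared": 0.58, "p_max": 0.001,
                "note": "constant printed as 0.000 (rounded); not invertible"}
  }
}
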