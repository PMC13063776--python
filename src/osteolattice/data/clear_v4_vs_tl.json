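{
  "label": "ClearV4-vs-tL",
  "laws": {
    "E": {"constant": 1168.59, "exponent": 2.06, "r_squared": 0.96, "p_max": 0.001},
    "sigma_y": {"constant": 71.83, "exponent": 2.91, "r_squared": 0.96, "p_max": 0.001},
    "sigma_p": {"constant": 67.13, "exponent": 3.65, "r_squared": 0.91, "p_max": 0.001}
  }
}
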