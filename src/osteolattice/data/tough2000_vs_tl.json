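{
  "label": "Tough2000-vs-tL",
  "laws": {
    "E": {"constant": 609.53, "exponent": 1.66, "r_squared": 0.87, "p_max": 0.001},
    "sigma_y": {"constant": 33.32, "exponent": 2.51, "r_squared": 0.93, "p_max": 0.001},
    "sigma_p": {"constant": 58.88, "exponent": 3.05, "r_squared": 0.96, "p_max": 0.001}
  }
}
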