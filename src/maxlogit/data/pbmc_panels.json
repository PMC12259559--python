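{
  "GSE9960": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -40.9212, "transform": "ln1p",
       "coefficients": {"RNF4": 8.0182, "HTR2C": 52.3501, "CHCHD4": -36.7917}},
      {"intercept": -25.4168, "transform": "ln1p",
       "coefficients": {"RNF4": -0.8774, "AC126474.2": -29.9838, "244479_at": 56.5659}}
    ],
    "reported_percent": {"accuracy": 95.71, "sensitivity": 96.30, "specificity": 93.75}
  }
}
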