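{
  "GSE65682": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -2.7350, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 2.3794, "FCAR": -8.07, "NONO": 0.0442}},
      {"intercept": 8.8323, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 11.1401, "RNF4": -8.24, "NONO": -4.2700}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE28750": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -17.7260, "transform": "log2_as_given",
       "coefficients": {"FCAR": 3.507}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE57065": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -23.9523, "transform": "log2_as_given",
       "coefficients": {"FCAR": 5.6255}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE95233": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -16.8988, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 0.6058, "RNF4": -4.828, "FCAR": 6.4325}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE69528": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -11.4506, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 6.3675, "FCAR": 1.8438, "NONO": -5.6657}}
    ],
    "reported_percent": {"accuracy": 97.10, "sensitivity": 95.18, "specificity": 100.00}
  },
  "GSE131761": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -17.1026, "transform": "log2_as_given",
       "coefficients": {"FCAR": 2.0143}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE154918": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": 30.0238, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 8.0139, "RNF4": -14.7455, "FCAR": 3.9406}}
    ],
    "reported_percent": {"accuracy": 95.24, "sensitivity": 94.94, "specificity": 96.15}
  },
  "GSE154918_shock_vs_sepsis": {
    "positive_class": "septic_shock", "control_class": "sepsis",
    "factors": [
      {"intercept": -25.8088, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 9.3795, "RNF4": -11.7651, "NONO": 2.0071}},
      {"intercept": 21.8625, "transform": "log2_as_given",
       "coefficients": {"CKAP4": -6.1460, "RNF4": -2.5326, "FCAR": 7.3024}},
      {"intercept": 197.1369, "transform": "log2_as_given",
       "coefficients": {"RNF4": -52.9581, "FCAR": 2.5032, "NONO": 33.043}}
    ],
    "reported_percent": {"accuracy": 92.31, "sensitivity": 94.74, "specificity": 90.00}
  },
  "GSE9692": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": 1.7772, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 7.2055, "OGFOD3": -16.4062}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE9692_alt_rnf4_ogfod3": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": 22.6871, "transform": "log2_as_given",
       "coefficients": {"RNF4": 1.9885, "OGFOD3": -28.0567}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE9692_alt_ckap4_rnf4": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -3.2680, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 5.7759, "RNF4": -8.34}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE13904": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": 8.3383, "transform": "log2_as_given",
       "coefficients": {"RNF4": 0.5639, "FCAR": 0.9597, "OGFOD3": -11.1228}},
      {"intercept": 4.5817, "transform": "log2_as_given",
       "coefficients": {"RNF4": -10.46, "RNASE2": 8.5348, "OGFOD3": -9.2377}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE49757": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": 64.0608, "transform": "log2_as_given",
       "coefficients": {"CKAP4": 6.8444, "FCAR": -10.22, "PLEKHO1": -4.7724}},
      {"intercept": -5.6928, "transform": "log2_as_given",
       "coefficients": {"CKAP4": -12.743, "PLEKHO1": 0.8999, "BMP6": 14.5114}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "GSE49757_severe_vs_sepsis": {
    "positive_class": "severe_sepsis", "control_class": "sepsis",
    "factors": [
      {"intercept": 105.1717, "transform": "log2_as_given",
       "coefficients": {"CKAP4": -27.0928, "NONO": 14.1109, "PLEKHO1": -56.3939, "BMP6": 24.3984}}
    ],
    "reported_percent": {"accuracy": 97.14, "sensitivity": 100.00, "specificity": 93.33}
  },
  "selfcollected_sepsis_vs_healthy": {
    "positive_class": "sepsis", "control_class": "healthy",
    "factors": [
      {"intercept": -2.7514, "transform": "identity",
       "coefficients": {"RNF4": 1.0879, "NONO": -6.5770, "PLEKHO1": -9.6589}}
    ],
    "reported_percent": {"accuracy": 100.00, "sensitivity": 100.00, "specificity": 100.00}
  },
  "selfcollected_shock_vs_sepsis": {
    "positive_class": "septic_shock", "control_class": "sepsis",
    "factors": [
      {"intercept": 5.4025, "transform": "identity",
       "coefficients": {"CKAP4": -0.1555, "FCAR": -7.7554, "PLEKHO1": 5.3968}},
      {"intercept": -11.4285, "transform": "identity",
       "coefficients": {"FCAR": 7.0408, "NONO": 0.0029, "PLEKHO1": -1.5894}},
      {"intercept": 4.1299, "transform": "identity",
       "coefficients": {"FCAR": -9.5293, "PLEKHO1": 1.6554, "BMP6": -0.0370}}
    ],
    "reported_percent": {"accuracy": 93.75, "sensitivity": 81.82, "specificity": 100.00}
  }
}
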