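{
  "name": "FHS",
  "horizon_years": 10,
  "strata_by": "sex",
  "required_inputs": ["age", "sex", "total_cholesterol", "hdl", "sbp", "bp_treated", "smoker", "diabetes"],
  "metadata": {
    "source": "D'Agostino et al., Circulation 2008 (general CVD profile, sex-specific Cox model)",
    "note": "Coefficients apply to ln-transformed continuous inputs; stratum center is the published mean linear predictor."
  },
  "strata": {
    "male": {
      "baseline_survival": 0.88936,
      "center": 23.9802,
      "terms": [
        {"inputs": ["age"], "transforms": ["log"], "coefficient": 3.06117},
        {"inputs": ["total_cholesterol"], "transforms": ["log"], "coefficient": 1.12370},
        {"inputs": ["hdl"], "transforms": ["log"], "coefficient": -0.93263},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 1.93303, "condition": {"input": "bp_treated", "equals": 0}},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 1.99881, "condition": {"input": "bp_treated", "equals": 1}},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 0.65451},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.57367}
      ]
    },
    "female": {
      "baseline_survival": 0.95012,
      "center": 26.1931,
      "terms": [
        {"inputs": ["age"], "transforms": ["log"], "coefficient": 2.32888},
        {"inputs": ["total_cholesterol"], "transforms": ["log"], "coefficient": 1.20904},
        {"inputs": ["hdl"], "transforms": ["log"], "coefficient": -0.70833},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 2.76157, "condition": {"input": "bp_treated", "equals": 0}},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 2.82263, "condition": {"input": "bp_treated", "equals": 1}},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 0.52873},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.69154}
      ]
    }
  }
}
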