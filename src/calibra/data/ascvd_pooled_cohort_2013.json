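{
  "name": "ASCVD",
  "horizon_years": 10,
  "strata_by": "sex",
  "required_inputs": ["age", "sex", "total_cholesterol", "hdl", "sbp", "bp_treated", "smoker", "diabetes"],
  "metadata": {
    "source": "Goff et al., 2013 ACC/AHA pooled cohort equations (white strata)",
    "note": "Interaction terms are products of ln-transformed inputs; stratum center is the published mean coefficient-value sum."
  },
  "strata": {
    "male": {
      "baseline_survival": 0.9144,
      "center": 61.18,
      "terms": [
        {"inputs": ["age"], "transforms": ["log"], "coefficient": 12.344},
        {"inputs": ["total_cholesterol"], "transforms": ["log"], "coefficient": 11.853},
        {"inputs": ["age", "total_cholesterol"], "transforms": ["log", "log"], "coefficient": -2.664},
        {"inputs": ["hdl"], "transforms": ["log"], "coefficient": -7.990},
        {"inputs": ["age", "hdl"], "transforms": ["log", "log"], "coefficient": 1.769},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 1.797, "condition": {"input": "bp_treated", "equals": 1}},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 1.764, "condition": {"input": "bp_treated", "equals": 0}},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 7.837},
        {"inputs": ["age", "smoker"], "transforms": ["log", "identity"], "coefficient": -1.795},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.658}
      ]
    },
    "female": {
      "baseline_survival": 0.9665,
      "center": -29.18,
      "terms": [
        {"inputs": ["age"], "transforms": ["log"], "coefficient": -29.799},
        {"inputs": ["age", "age"], "transforms": ["log", "log"], "coefficient": 4.884},
        {"inputs": ["total_cholesterol"], "transforms": ["log"], "coefficient": 13.540},
        {"inputs": ["age", "total_cholesterol"], "transforms": ["log", "log"], "coefficient": -3.114},
        {"inputs": ["hdl"], "transforms": ["log"], "coefficient": -13.578},
        {"inputs": ["age", "hdl"], "transforms": ["log", "log"], "coefficient": 3.149},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 2.019, "condition": {"input": "bp_treated", "equals": 1}},
        {"inputs": ["sbp"], "transforms": ["log"], "coefficient": 1.957, "condition": {"input": "bp_treated", "equals": 0}},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 7.574},
        {"inputs": ["age", "smoker"], "transforms": ["log", "identity"], "coefficient": -1.665},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.661}
      ]
    }
  }
}
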