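{
  "name": "INDANA",
  "horizon_years": 5,
  "strata_by": "sex",
  "required_inputs": ["age", "sex", "sbp", "smoker", "diabetes", "creatinine", "prior_mi", "prior_stroke"],
  "metadata": {
    "source": "SYNTHETIC reconstruction of an INDANA-style hypertension-trial risk calculator (Cox form with age, blood pressure, smoking, diabetes, serum creatinine, prior MI/stroke).",
    "note": "The original calculator's published coefficients are not reproduced here; these representative values preserve its input set, directionality and rough effect magnitudes for structural and computability testing only."
  },
  "strata": {
    "male": {
      "baseline_survival": 0.93,
      "center": 0.0,
      "terms": [
        {"inputs": ["age"], "transforms": ["identity"], "coefficient": 0.050, "center": 65},
        {"inputs": ["sbp"], "transforms": ["identity"], "coefficient": 0.012, "center": 140},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 0.50},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.60},
        {"inputs": ["creatinine"], "transforms": ["log"], "coefficient": 0.55, "center": 0.1823},
        {"inputs": ["prior_mi"], "transforms": ["identity"], "coefficient": 0.60},
        {"inputs": ["prior_stroke"], "transforms": ["identity"], "coefficient": 0.70}
      ]
    },
    "female": {
      "baseline_survival": 0.95,
      "center": 0.0,
      "terms": [
        {"inputs": ["age"], "transforms": ["identity"], "coefficient": 0.050, "center": 65},
        {"inputs": ["sbp"], "transforms": ["identity"], "coefficient": 0.012, "center": 140},
        {"inputs": ["smoker"], "transforms": ["identity"], "coefficient": 0.50},
        {"inputs": ["diabetes"], "transforms": ["identity"], "coefficient": 0.60},
        {"inputs": ["creatinine"], "transforms": ["log"], "coefficient": 0.55, "center": 0.1823},
        {"inputs": ["prior_mi"], "transforms": ["identity"], "coefficient": 0.60},
        {"inputs": ["prior_stroke"], "transforms": ["identity"], "coefficient": 0.70}
      ]
    }
  }
}
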