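{
  "comment": "Default 31-variable configuration for the naive-Bayes CV-risk network. Cut-points are conventional clinical bins (KDIGO G-stages for eGFR, KDIGO albuminuria categories for the ACR/24h-urine-protein node, NCEP/WHO bins elsewhere) and are editable. State prevalences are marginals for an elderly non-dialysis CKD clinic population; reference-state prevalences are implied remainders and listed for documentation only.",
  "variables": [
    {"name": "age", "kind": "continuous-discretized", "units": "years",
     "states": ["<45", "45-54", "55-64", "65-74", ">=75"], "cutpoints": [45, 55, 65, 75],
     "reference_state": "65-74",
     "prevalences": {"<45": 0.05, "45-54": 0.10, "55-64": 0.22, "65-74": 0.35, ">=75": 0.28}},
    {"name": "gender", "kind": "categorical",
     "states": ["female", "male"], "reference_state": "female",
     "prevalences": {"female": 0.48, "male": 0.52}},
    {"name": "hdl_cholesterol", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["low", "normal", "high"], "cutpoints": [40, 60], "reference_state": "normal",
     "prevalences": {"low": 0.30, "normal": 0.45, "high": 0.25}},
    {"name": "ldl_cholesterol", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["optimal", "above-optimal", "high"], "cutpoints": [100, 160], "reference_state": "optimal",
     "prevalences": {"optimal": 0.40, "above-optimal": 0.45, "high": 0.15}},
    {"name": "bmi", "kind": "continuous-discretized", "units": "kg/m2",
     "states": ["underweight", "normal", "overweight", "obese", "severely-obese"],
     "cutpoints": [18.5, 25, 30, 40], "reference_state": "normal",
     "prevalences": {"underweight": 0.03, "normal": 0.27, "overweight": 0.35, "obese": 0.30, "severely-obese": 0.05}},
    {"name": "triglyceride", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["normal", "high", "very-high"], "cutpoints": [150, 500], "reference_state": "normal",
     "prevalences": {"normal": 0.55, "high": 0.40, "very-high": 0.05}},
    {"name": "diabetes", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.60, "yes": 0.40}},
    {"name": "hypertension", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.20, "yes": 0.80}},
    {"name": "smoking", "kind": "categorical",
     "states": ["never", "ex-smoker", "smoker"], "reference_state": "never",
     "prevalences": {"never": 0.63, "ex-smoker": 0.25, "smoker": 0.12}},
    {"name": "cerebrovascular_disease", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.91, "yes": 0.09}},
    {"name": "coronary_artery_disease", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.81, "yes": 0.19}},
    {"name": "congestive_heart_failure", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.88, "yes": 0.12}},
    {"name": "peripheral_vascular_disease", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.91, "yes": 0.09}},
    {"name": "atrial_fibrillation", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.87, "yes": 0.13}},
    {"name": "glucose", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["normal", "impaired", "high"], "cutpoints": [100, 126], "reference_state": "normal",
     "prevalences": {"normal": 0.45, "impaired": 0.30, "high": 0.25}},
    {"name": "hstnt", "kind": "continuous-discretized", "units": "ng/l",
     "states": ["normal", "elevated", "high"], "cutpoints": [14, 52], "reference_state": "normal",
     "prevalences": {"normal": 0.55, "elevated": 0.35, "high": 0.10}},
    {"name": "il6", "kind": "continuous-discretized", "units": "ng/l",
     "states": ["normal", "elevated", "high"], "cutpoints": [2, 6], "reference_state": "normal",
     "prevalences": {"normal": 0.45, "elevated": 0.35, "high": 0.20}},
    {"name": "pth", "kind": "continuous-discretized", "units": "ng/l",
     "states": ["normal", "elevated", "high"], "cutpoints": [65, 300], "reference_state": "normal",
     "prevalences": {"normal": 0.45, "elevated": 0.45, "high": 0.10}},
    {"name": "anemia", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.65, "yes": 0.35}},
    {"name": "alcohol", "kind": "categorical",
     "states": ["abstinent", "moderate", "abuse"], "reference_state": "abstinent",
     "prevalences": {"abstinent": 0.35, "moderate": 0.45, "abuse": 0.20}},
    {"name": "cancer", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.89, "yes": 0.11}},
    {"name": "copd", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.93, "yes": 0.07}},
    {"name": "connective_tissue_disorder", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.98, "yes": 0.02}},
    {"name": "liver_disease", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.96, "yes": 0.04}},
    {"name": "psychiatric_disease", "kind": "binary", "states": ["no", "yes"], "reference_state": "no",
     "prevalences": {"no": 0.99, "yes": 0.01}},
    {"name": "albumin", "kind": "continuous-discretized", "units": "g/dl",
     "states": ["severe-low", "low", "normal"], "cutpoints": [3.0, 3.5], "reference_state": "normal",
     "prevalences": {"severe-low": 0.05, "low": 0.20, "normal": 0.75}},
    {"name": "albuminuria", "kind": "continuous-discretized", "units": "mg/mmol (ACR)",
     "states": ["A1", "A2", "A3"], "cutpoints": [3, 30], "reference_state": "A1",
     "channels": {"urine_protein_g_24h": [0.15, 0.5]},
     "prevalences": {"A1": 0.40, "A2": 0.35, "A3": 0.25}},
    {"name": "crp", "kind": "continuous-discretized", "units": "mg/l",
     "states": ["normal", "elevated", "high"], "cutpoints": [3, 10], "reference_state": "normal",
     "prevalences": {"normal": 0.45, "elevated": 0.35, "high": 0.20}},
    {"name": "egfr", "kind": "continuous-discretized", "units": "ml/min/1.73m2",
     "states": ["G5", "G4", "G3b", "G3a", "G2", "G1"], "cutpoints": [15, 30, 45, 60, 90],
     "reference_state": "G3b",
     "prevalences": {"G5": 0.06, "G4": 0.25, "G3b": 0.30, "G3a": 0.22, "G2": 0.15, "G1": 0.02}},
    {"name": "phosphate", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["low", "normal", "high"], "cutpoints": [2.5, 4.5], "reference_state": "normal",
     "prevalences": {"low": 0.05, "normal": 0.75, "high": 0.20}},
    {"name": "uric_acid", "kind": "continuous-discretized", "units": "mg/dl",
     "states": ["normal", "high"], "cutpoints": [7], "reference_state": "normal",
     "prevalences": {"normal": 0.65, "high": 0.35}}
  ]
}
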