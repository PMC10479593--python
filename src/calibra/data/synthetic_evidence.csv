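study_id,variable,exposure_state,measure,point,ci_low,ci_high,n,followup_years,pediatric,rrt,other_disease
S01,age,<45,OR,0.30,0.21,0.43,6500,5,0,0,0
S02,age,45-54,OR,0.50,0.38,0.66,6500,5,0,0,0
S03,age,55-64,OR,0.75,0.60,0.94,6500,5,0,0,0
S04,age,>=75,OR,1.60,1.31,1.95,6500,5,0,0,0
S05,gender,male,OR,1.30,1.12,1.51,14000,4,0,0,0
S06,hdl_cholesterol,low,OR,1.40,1.15,1.70,5200,6,0,0,0
S07,hdl_cholesterol,high,OR,0.85,0.70,1.03,5200,6,0,0,0
S08,ldl_cholesterol,above-optimal,OR,1.20,1.00,1.44,4800,6,0,0,0
S09,ldl_cholesterol,high,OR,1.50,1.19,1.89,4800,6,0,0,0
S10,bmi,underweight,OR,1.40,1.05,1.87,9000,3,0,0,0
S11,bmi,overweight,OR,1.10,0.96,1.26,9000,3,0,0,0
S12,bmi,obese,OR,1.30,1.11,1.52,9000,3,0,0,0
S13,bmi,severely-obese,OR,1.60,1.22,2.10,9000,3,0,0,0
S14,triglyceride,high,OR,1.20,1.02,1.41,5600,5,0,0,0
S15,triglyceride,very-high,OR,1.50,1.12,2.01,5600,5,0,0,0
S16,diabetes,yes,OR,1.80,1.52,2.13,5000,4,0,0,0
S17,diabetes,yes,OR,2.10,1.86,2.37,12000,6,0,0,0
S18,diabetes,yes,OR,2.20,1.73,2.80,3000,3,0,0,0
S19,hypertension,yes,OR,1.40,1.21,1.62,8000,5,0,0,0
S20,hypertension,yes,OR,1.65,1.39,1.96,6000,4,0,0,0
S21,smoking,ex-smoker,OR,1.25,1.05,1.49,9000,8,0,0,0
S22,smoking,smoker,OR,1.70,1.38,2.09,4000,8,0,0,0
S23,smoking,smoker,OR,1.90,1.58,2.28,5000,6,0,0,0
S24,cerebrovascular_disease,yes,OR,1.90,1.54,2.34,7400,3,0,0,0
S25,coronary_artery_disease,yes,OR,2.20,1.90,2.55,11000,4,0,0,0
S26,congestive_heart_failure,yes,OR,2.50,2.08,3.00,8200,3,0,0,0
S27,peripheral_vascular_disease,yes,OR,1.80,1.45,2.23,6100,4,0,0,0
S28,atrial_fibrillation,yes,OR,1.90,1.57,2.30,7700,3,0,0,0
S29,glucose,impaired,OR,1.20,1.02,1.41,6800,5,0,0,0
S30,glucose,high,OR,1.50,1.25,1.80,6800,5,0,0,0
S31,hstnt,elevated,OR,1.80,1.46,2.22,3900,2,0,0,0
S32,hstnt,high,RR,3.00,2.31,3.90,3900,2,0,0,0
S33,il6,elevated,OR,1.40,1.13,1.73,3100,3,0,0,0
S34,il6,high,OR,2.00,1.55,2.58,3100,3,0,0,0
S35,pth,elevated,OR,1.15,0.97,1.36,5400,4,0,0,0
S36,pth,high,OR,1.50,1.19,1.89,5400,4,0,0,0
S37,anemia,yes,HR,1.50,1.28,1.76,10200,5,0,0,0
S38,alcohol,moderate,OR,0.85,0.72,1.00,8800,7,0,0,0
S39,alcohol,abuse,OR,1.40,1.13,1.73,8800,7,0,0,0
S40,cancer,yes,OR,1.20,0.99,1.45,9600,4,0,0,0
S41,copd,yes,OR,1.60,1.29,1.98,8300,4,0,0,0
S42,connective_tissue_disorder,yes,OR,1.30,0.93,1.82,4400,5,0,0,0
S43,liver_disease,yes,OR,1.30,0.99,1.71,5100,5,0,0,0
S44,psychiatric_disease,yes,OR,1.20,0.84,1.72,4900,5,0,0,0
S45,albumin,severe-low,OR,2.20,1.70,2.85,7200,3,0,0,0
S46,albumin,low,OR,1.50,1.24,1.81,7200,3,0,0,0
S47,albuminuria,A2,OR,1.50,1.27,1.77,12600,5,0,0,0
S48,albuminuria,A3,OR,2.20,1.85,2.62,12600,5,0,0,0
S49,crp,elevated,OR,1.40,1.16,1.69,6600,4,0,0,0
S50,crp,high,OR,2.00,1.62,2.47,6600,4,0,0,0
S51,egfr,G5,OR,2.20,1.71,2.83,7000,4,0,0,0
S52,egfr,G4,OR,1.45,1.21,1.74,7000,4,0,0,0
S53,egfr,G4,OR,1.55,1.27,1.89,7000,3,0,0,0
S54,egfr,G3a,OR,0.90,0.76,1.07,7000,4,0,0,0
S55,egfr,G2,OR,0.80,0.65,0.98,7000,4,0,0,0
S56,egfr,G1,OR,0.70,0.49,1.00,7000,4,0,0,0
S57,phosphate,low,OR,1.10,0.85,1.42,6900,4,0,0,0
S58,phosphate,high,OR,1.40,1.16,1.69,6900,4,0,0,0
S59,uric_acid,high,OR,1.30,1.10,1.54,8700,5,0,0,0
X60,diabetes,yes,OR,2.60,1.90,3.56,2200,0.5,0,0,0
X61,bmi,obese,OR,1.90,1.30,2.78,1500,3,1,0,0
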