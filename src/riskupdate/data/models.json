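{
  "cambridge": {
    "label": "Cambridge Diabetes Risk model",
    "intercept": -6.322,
    "terms": [
      {"name": "female", "kind": "derived-binary", "coefficient": -0.879,
       "rule": {"type": "equals", "field": "sex", "value": "F"},
       "reference": "male"},
      {"name": "antihypertensive_meds", "kind": "binary", "coefficient": 1.222,
       "rule": {"type": "flag", "field": "antihypertensive_meds"},
       "reference": "no antihypertensive medication"},
      {"name": "corticosteroids", "kind": "binary", "coefficient": 2.191,
       "rule": {"type": "flag", "field": "corticosteroids"},
       "reference": "no prescribed steroids"},
      {"name": "age", "kind": "continuous", "coefficient": 0.063,
       "rule": {"type": "linear", "field": "age"},
       "reference": "per year"},
      {"name": "bmi_25_to_27.5", "kind": "categorical", "coefficient": 0.699,
       "rule": {"type": "range", "field": "bmi", "lo": 25.0, "hi": 27.5},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "bmi_27.5_to_30", "kind": "categorical", "coefficient": 1.97,
       "rule": {"type": "range", "field": "bmi", "lo": 27.5, "hi": 30.0},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "bmi_30_plus", "kind": "categorical", "coefficient": 2.518,
       "rule": {"type": "range", "field": "bmi", "lo": 30.0, "hi": null},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "fh_parent_or_sibling", "kind": "derived-binary", "coefficient": 0.728,
       "rule": {"type": "family", "combine": "parent_or_sibling_exclusive"},
       "family": "family_history", "reference": "no parent or sibling with diabetes"},
      {"name": "fh_parent_and_sibling", "kind": "derived-binary", "coefficient": 0.753,
       "rule": {"type": "family", "combine": "parent_and_sibling"},
       "family": "family_history", "reference": "no parent or sibling with diabetes"},
      {"name": "ex_smoker", "kind": "categorical", "coefficient": -0.218,
       "rule": {"type": "equals", "field": "smoking", "value": "ex"},
       "family": "smoking", "reference": "never smoked"},
      {"name": "current_smoker", "kind": "categorical", "coefficient": 0.855,
       "rule": {"type": "equals", "field": "smoking", "value": "current"},
       "family": "smoking", "reference": "never smoked"}
    ],
    "fixed_zero_terms": []
  },
  "kuwaiti": {
    "label": "Kuwaiti Risk model",
    "intercept": -5.018,
    "terms": [
      {"name": "fh_sibling", "kind": "derived-binary", "coefficient": 0.979,
       "rule": {"type": "family", "combine": "sibling"},
       "reference": "no sibling with diabetes"},
      {"name": "antihypertensive_meds", "kind": "binary", "coefficient": 0.978,
       "rule": {"type": "flag", "field": "antihypertensive_meds"},
       "reference": "no antihypertensive medication"},
      {"name": "age_35_plus", "kind": "derived-binary", "coefficient": 1.315,
       "rule": {"type": "range", "field": "age", "lo": 35.0, "hi": null},
       "family": "age_band", "reference": "age < 35 years"},
      {"name": "wc_over_100", "kind": "derived-binary", "coefficient": 1.93,
       "rule": {"type": "threshold", "field": "waist", "gt": 100.0},
       "reference": "waist circumference <= 100 cm"}
    ],
    "fixed_zero_terms": []
  },
  "omani": {
    "label": "Omani Diabetes Risk model",
    "intercept": -4.7,
    "terms": [
      {"name": "age_40_to_59", "kind": "categorical", "coefficient": 1.8,
       "rule": {"type": "range", "field": "age", "lo": 40.0, "hi": 60.0},
       "family": "age_band", "reference": "age < 40 years"},
      {"name": "age_60_plus", "kind": "categorical", "coefficient": 2.3,
       "rule": {"type": "range", "field": "age", "lo": 60.0, "hi": null},
       "family": "age_band", "reference": "age < 40 years"},
      {"name": "wc_high", "kind": "derived-binary", "coefficient": 0.38,
       "rule": {"type": "sex_range", "field": "waist",
                "male": {"lo": 94.0, "hi": null}, "female": {"lo": 80.0, "hi": null}},
       "reference": "waist circumference below the sex-specific cutoff"},
      {"name": "bmi_25_to_30", "kind": "categorical", "coefficient": 0.54,
       "rule": {"type": "range", "field": "bmi", "lo": 25.0, "hi": 30.0},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "bmi_30_plus", "kind": "categorical", "coefficient": 0.69,
       "rule": {"type": "range", "field": "bmi", "lo": 30.0, "hi": null},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "fh_parent_or_sibling_any", "kind": "derived-binary", "coefficient": 1.9,
       "rule": {"type": "family", "combine": "parent_or_sibling"},
       "reference": "no parent or sibling with diabetes"},
      {"name": "elevated_bp", "kind": "derived-binary", "coefficient": 0.73,
       "rule": {"type": "bp_either", "sbp_ge": 140.0, "dbp_ge": 90.0},
       "reference": "SBP < 140 mmHg and DBP < 90 mmHg"}
    ],
    "fixed_zero_terms": []
  },
  "rotterdam": {
    "label": "Rotterdam Predictive model",
    "intercept": -3.02,
    "terms": [
      {"name": "age_55_75_increments", "kind": "continuous", "coefficient": 0.19,
       "rule": {"type": "age_increments", "start": 55.0, "step": 5.0, "cap": 5},
       "reference": "per completed 5-year increment above 55, 0 below 55, capped at 5"},
      {"name": "male", "kind": "derived-binary", "coefficient": 0.46,
       "rule": {"type": "equals", "field": "sex", "value": "M"},
       "reference": "female"},
      {"name": "antihypertensive_meds", "kind": "binary", "coefficient": 0.42,
       "rule": {"type": "flag", "field": "antihypertensive_meds"},
       "reference": "no antihypertensive medication"},
      {"name": "bmi_30_plus", "kind": "derived-binary", "coefficient": 0.51,
       "rule": {"type": "range", "field": "bmi", "lo": 30.0, "hi": null},
       "family": "bmi_band", "reference": "BMI < 30 kg/m^2"}
    ],
    "fixed_zero_terms": []
  },
  "finnish": {
    "label": "Simplified Finnish Diabetes Risk model",
    "intercept": -5.514,
    "terms": [
      {"name": "age_45_to_54", "kind": "categorical", "coefficient": 0.628,
       "rule": {"type": "range", "field": "age", "lo": 45.0, "hi": 55.0},
       "family": "age_band", "reference": "age < 45 years"},
      {"name": "age_55_to_64", "kind": "categorical", "coefficient": 0.892,
       "rule": {"type": "range", "field": "age", "lo": 55.0, "hi": 65.0},
       "family": "age_band", "reference": "age < 45 years"},
      {"name": "bmi_25_to_30", "kind": "categorical", "coefficient": 0.165,
       "rule": {"type": "range", "field": "bmi", "lo": 25.0, "hi": 30.0},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "bmi_30_plus", "kind": "categorical", "coefficient": 1.096,
       "rule": {"type": "range", "field": "bmi", "lo": 30.0, "hi": null},
       "family": "bmi_band", "reference": "BMI < 25 kg/m^2"},
      {"name": "wc_mid", "kind": "categorical", "coefficient": 0.857,
       "rule": {"type": "sex_range", "field": "waist",
                "male": {"lo": 94.0, "hi": 102.0}, "female": {"lo": 80.0, "hi": 88.0}},
       "family": "wc_band", "reference": "waist circumference below the sex-specific cutoff"},
      {"name": "wc_high", "kind": "categorical", "coefficient": 1.35,
       "rule": {"type": "sex_range", "field": "waist",
                "male": {"lo": 102.0, "hi": null}, "female": {"lo": 88.0, "hi": null}},
       "family": "wc_band", "reference": "waist circumference below the sex-specific cutoff"},
      {"name": "antihypertensive_meds", "kind": "binary", "coefficient": 0.711,
       "rule": {"type": "flag", "field": "antihypertensive_meds"},
       "reference": "no antihypertensive medication"}
    ],
    "fixed_zero_terms": ["history_high_blood_glucose"]
  }
}
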