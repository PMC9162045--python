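{
  "name": "general-cvd-office-bmi",
  "version": "1.0",
  "description": "Sex-specific Cox coefficients for the office-based (non-laboratory, BMI) general cardiovascular disease 10-year risk function. risk = 1 - s0 ** exp(lp - lp_mean), lp = b_ln_age*ln(age) + b_ln_bmi*ln(bmi) + b_ln_sbp*ln(sbp) (treated or untreated coefficient by antihypertensive-medication status) + b_smoker*smoker + b_diabetes*diabetes.",
  "male": {
    "b_ln_age": 3.11296,
    "b_ln_bmi": 0.79277,
    "b_ln_sbp_untreated": 1.85508,
    "b_ln_sbp_treated": 1.92672,
    "b_smoker": 0.70953,
    "b_diabetes": 0.5316,
    "s0": 0.88431,
    "lp_mean": 23.9388
  },
  "female": {
    "b_ln_age": 2.72107,
    "b_ln_bmi": 0.51125,
    "b_ln_sbp_untreated": 2.81291,
    "b_ln_sbp_treated": 2.88267,
    "b_smoker": 0.61868,
    "b_diabetes": 0.77763,
    "s0": 0.94833,
    "lp_mean": 26.0145
  }
}
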