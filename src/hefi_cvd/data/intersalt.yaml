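# Spot-urine -> 24-h urinary sodium prediction (INTERSALT, without dietary
# data). Sex-specific linear predictors on casual urinary concentrations plus
# anthropometry; the female equation carries a quadratic age term.
#
# Units: urinary sodium / potassium / creatinine in mmol/L; BMI in kg/m^2;
# age in years. The linear predictor is 24-h sodium excretion in mmol/24 h,
# converted to mg/24 h with 23 mg per mmol.
version: "intersalt-nodiet-1"
mg_per_mmol: 23.0
male:
  intercept: 25.46
  urine_na: 0.46
  urine_k: -0.13
  urine_cr: -2.75
  bmi: 4.10
  age: 0.26
  age2: 0.0
female:
  intercept: 5.07
  urine_na: 0.34
  urine_k: -0.09
  urine_cr: -2.16
  bmi: 2.39
  age: 2.35
  age2: -0.03
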