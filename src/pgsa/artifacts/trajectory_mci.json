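{
 "kind": "trajectory",
 "terms": [
  "intercept",
  "bmi2",
  "bmi3",
  "visit",
  "apoe4",
  "age",
  "faq",
  "adascog_bl",
  "npbatt_bl",
  "visit:bmi2",
  "visit:bmi3",
  "visit:apoe4",
  "visit:adascog_bl",
  "age:faq"
 ],
 "coefficients": [
  0.92879,
  -0.06911,
  -0.04498,
  0.01241,
  0.03383,
  -0.00887,
  -0.11273,
  -0.00299,
  0.97529,
  0.0213,
  0.05513,
  -0.03558,
  -0.00557,
  0.0014
 ],
 "covariance": [
  [
   0.0514518489,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0014531344000000002,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0028483569,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0004769855999999999,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0006801664,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   8.526399999999999e-06,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0014707225000000002,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.1492099999999998e-05,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0009114361000000001,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0001865956,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0004012009,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   8.68624e-05,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   1.0815999999999997e-06,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   2.6010000000000006e-07
  ]
 ],
 "random_effects": {
  "sd_intercept": 0.1856,
  "sd_slope": 0.0677,
  "corr": 0.6544
 },
 "within_sd": 0.25,
 "n": 375,
 "n_obs": 0,
 "time_coding": "visit_6mo",
 "random_slopes": true,
 "boundary": false,
 "coding": {
  "gender_reference": "male",
  "bmi_cutoffs": [
   25.0,
   30.0
  ],
  "obesity_definition": "bmi3"
 },
 "provenance": {
  "source": "reference ADNI-MCI trajectory model (published fixed effects and variance components)",
  "note": "fixed-effect covariance is a diagonal approximation from standard errors"
 }
}
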