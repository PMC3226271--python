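{
 "kind": "trajectory",
 "terms": [
  "intercept",
  "visit",
  "csf_ratio",
  "faq",
  "adascog_bl",
  "npbatt_bl",
  "visit:csf_ratio",
  "visit:adascog_bl"
 ],
 "coefficients": [
  0.19832,
  -0.07163,
  0.00328,
  -0.01015,
  0.00058,
  0.99973,
  0.02229,
  -0.00398
 ],
 "covariance": [
  [
   0.0087890625,
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
   0.0011195715999999997,
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
   0.00023562250000000004,
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
   2.5806400000000004e-05,
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
   2.1436899999999995e-05,
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
   0.0019123128999999999,
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
   3.0030399999999996e-05,
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
   2.1315999999999996e-06
  ]
 ],
 "random_effects": {
  "sd_intercept": 0.1816,
  "sd_slope": 0.0698,
  "corr": 0.5598
 },
 "within_sd": 0.2512,
 "n": 189,
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
  "source": "reference trajectory model with CSF Abeta42/T-tau covariate (lumbar-puncture subsample)",
  "note": "fixed-effect covariance is a diagonal approximation from standard errors"
 }
}
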