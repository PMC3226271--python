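{
 "kind": "endpoint",
 "terms": [
  "intercept",
  "gender",
  "obesity",
  "faq",
  "mmse",
  "adascog_bl",
  "npbatt_bl",
  "faq:npbatt_bl"
 ],
 "coefficients": [
  3.84232,
  0.28474,
  -0.27526,
  0.07902,
  -0.06994,
  0.0925,
  -0.50529,
  0.03762
 ],
 "covariance": [
  [
   0.5848119729,
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
   0.0070341769,
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
   0.01364224,
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
   0.0003193369,
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
   0.0006421156000000001,
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
   5.89824e-05,
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
   0.00777924,
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
   0.0001798281
  ]
 ],
 "residual_sd": 0.669,
 "n": 286,
 "transform": "sqrt",
 "coding": {
  "gender_reference": "male",
  "bmi_cutoffs": [
   25.0,
   30.0
  ],
  "obesity_definition": "bmi3"
 },
 "provenance": {
  "source": "reference ADNI-MCI endpoint model (published coefficients)",
  "note": "parameter covariance is a diagonal approximation from standard errors; off-diagonals were not published"
 }
}
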