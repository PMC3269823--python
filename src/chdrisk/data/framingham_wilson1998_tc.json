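{
  "name": "wilson1998_tc",
  "description": "Sex-specific Cox proportional-hazards coefficients for 10-year hard-CHD risk from the Framingham Heart Study (Wilson et al. 1998, total-cholesterol sheet). Continuous age (quadratic in women), JNC-V blood-pressure stages, NCEP cholesterol categories. 'reference' is the linear predictor evaluated at the Framingham population means; 's10' the baseline 10-year survival.",
  "covariate_ranges": {
    "age": [30.0, 74.0],
    "tc": [100.0, 405.0],
    "hdl": [10.0, 100.0],
    "sbp": [80.0, 220.0],
    "dbp": [40.0, 130.0]
  },
  "sex_models": {
    "male": {
      "terms": [
        {"covariate": "age", "type": "polynomial", "coefficients": [0.04826]},
        {"covariate": "tc", "type": "categorical",
         "edges": [160.0, 200.0, 240.0, 280.0],
         "coefficients": [-0.65945, 0.0, 0.17692, 0.50539, 0.65713]},
        {"covariate": "hdl", "type": "categorical",
         "edges": [35.0, 45.0, 50.0, 60.0],
         "coefficients": [0.49744, 0.2431, 0.0, -0.05107, -0.4866]},
        {"covariate": "bp", "type": "blood_pressure",
         "sbp_edges": [120.0, 130.0, 140.0, 160.0],
         "dbp_edges": [80.0, 85.0, 90.0, 100.0],
         "coefficients": [-0.00226, 0.0, 0.2832, 0.52168, 0.61859]},
        {"covariate": "diabetes", "type": "binary", "coefficients": [0.42839]},
        {"covariate": "smoker", "type": "binary", "coefficients": [0.52337]}
      ],
      "reference": 3.0975,
      "s10": 0.90015
    },
    "female": {
      "terms": [
        {"covariate": "age", "type": "polynomial", "coefficients": [0.33766, -0.00268]},
        {"covariate": "tc", "type": "categorical",
         "edges": [160.0, 200.0, 240.0, 280.0],
         "coefficients": [-0.26138, 0.0, 0.20771, 0.24385, 0.53513]},
        {"covariate": "hdl", "type": "categorical",
         "edges": [35.0, 45.0, 50.0, 60.0],
         "coefficients": [0.84312, 0.37796, 0.19785, 0.0, -0.42951]},
        {"covariate": "bp", "type": "blood_pressure",
         "sbp_edges": [120.0, 130.0, 140.0, 160.0],
         "dbp_edges": [80.0, 85.0, 90.0, 100.0],
         "coefficients": [-0.53363, 0.0, -0.06773, 0.26288, 0.46573]},
        {"covariate": "diabetes", "type": "binary", "coefficients": [0.59626]},
        {"covariate": "smoker", "type": "binary", "coefficients": [0.29246]}
      ],
      "reference": 9.92545,
      "s10": 0.96246
    }
  }
}
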