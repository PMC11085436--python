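{
  "schema_version": 1,
  "description": "Published coefficient sets and printed goodness-of-fit / validation statistics for the 13 LMA model forms. Coefficients are in canonical parameter order (see crownlma.model_library); values carry the printed (rounded) digits.",
  "models": [
    {"model_id": 1, "formula_text": "LMA = -38.47 * RDINC + 87.60", "parameter_names": ["a0", "a1"], "coefficients": [-38.47, 87.60], "ra2": 0.297, "rmse": 15.194, "aic": 6452.82},
    {"model_id": 2, "formula_text": "LMA = 90.53 * exp(-0.58 * RDINC)", "parameter_names": ["b0", "b1"], "coefficients": [90.53, -0.58], "ra2": 0.302, "rmse": 15.143, "aic": 6447.61},
    {"model_id": 3, "formula_text": "LMA = 27.98 * RDINC^2 - 68.36 * RDINC + 93.72", "parameter_names": ["c0", "c1", "c2"], "coefficients": [27.98, -68.36, 93.72], "ra2": 0.304, "rmse": 15.116, "aic": 6446.85},
    {"model_id": 4, "formula_text": "LMA = 55.33 * RDINC^-0.24", "parameter_names": ["d0", "d1"], "coefficients": [55.33, -0.24], "ra2": 0.299, "rmse": 15.171, "aic": 6450.54},
    {"model_id": 5, "formula_text": "LMA = -22.92 + 2.62 * (DOY - 120) + 0.02 * (DOY - 120)^2", "parameter_names": ["e0", "e1", "e2"], "coefficients": [0.02, 2.62, -22.92], "ra2": 0.403, "rmse": 14.002, "aic": 6327.61},
    {"model_id": 6, "formula_text": "LMA = 156.76 * LDMC + 15.56", "parameter_names": ["f0", "f1"], "coefficients": [156.76, 15.56], "ra2": 0.443, "rmse": 13.524, "aic": 6271.50},
    {"model_id": 7, "formula_text": "LMA = 157.82 * LDMC^0.76", "parameter_names": ["g0", "g1"], "coefficients": [157.82, 0.76], "ra2": 0.447, "rmse": 13.479, "aic": 6266.29},
    {"model_id": 8, "formula_text": "LMA = (-1.32 * (DOY-120) + 258.30) * LDMC + 0.31 * (DOY - 120) - 7.52", "parameter_names": ["h0", "h1", "h2", "h3"], "coefficients": [-1.32, 258.30, 0.31, -7.52], "ra2": 0.470, "rmse": 13.16, "aic": 4682.5, "me": -0.092, "mae": 10.753, "fi": 0.474},
    {"model_id": 9, "formula_text": "LMA = (-62.38 * RDINC + 150.84) * LDMC + 27.67", "parameter_names": ["i0", "i1", "i2"], "coefficients": [-62.38, 150.84, 27.67], "ra2": 0.507, "rmse": 12.69, "aic": 4638.0, "me": -0.106, "mae": 10.176, "fi": 0.514},
    {"model_id": 10, "formula_text": "LMA = (-41.15 * RDINC + 150.95) * LDMC^0.59", "parameter_names": ["j0", "j1", "j2"], "coefficients": [-41.15, 150.95, 0.59], "ra2": 0.515, "rmse": 12.59, "aic": 4629.0, "me": -0.099, "mae": 10.040, "fi": 0.523},
    {"model_id": 11, "formula_text": "LMA = (0.0003 * (DOY - 120)^3 - 0.114 * (DOY - 120)^2 + 11.38 * (DOY - 120) - 217.1) * LDMC + 32.28", "parameter_names": ["k0", "k1", "k2", "k3", "k4"], "coefficients": [0.0003, -0.114, 11.38, -217.1, 32.28], "ra2": 0.598, "rmse": 11.46, "aic": 4522.8, "me": -0.236, "mae": 9.353, "fi": 0.615},
    {"model_id": 12, "formula_text": "LMA = (-0.0215 * (DOY - 120)^2 + 3.256 * (DOY - 120) + 20.264) * LDMC^0.574", "parameter_names": ["l0", "l1", "l2", "l3"], "coefficients": [-0.0215, 3.256, 20.264, 0.574], "ra2": 0.593, "rmse": 11.54, "aic": 4528.3, "me": -0.205, "mae": 9.318, "fi": 0.611},
    {"model_id": 13, "formula_text": "LMA = (-37.08 * RDINC - 0.44) + (0.003 * RDINC + 2.524) * (DOY - 120) - 0.016 * (DOY - 120)^2", "parameter_names": ["m0", "m1", "m2", "m3", "m4"], "coefficients": [-37.08, -0.44, 0.003, 2.524, -0.016], "ra2": 0.678, "rmse": 10.25, "aic": 4390.5, "me": -0.154, "mae": 8.050, "fi": 0.682}
  ]
}
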