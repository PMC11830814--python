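{
  "schema": "lactodb-registry/1",
  "description": "Continuous functions of postpartum age (months, 0-12) for 13 maternal and milk parameters, with constant coefficients of variation, for use in lactation PBPK models.",
  "parameters": [
    {
      "id": "milk_volume",
      "name": "Daily milk production volume",
      "units": "L/day",
      "cv": 0.33,
      "distribution": "lognormal",
      "segments": [
        {"family": "hill", "t_lo": 0.0, "t_hi": 6.0,
         "coefficients": {"emax": 0.81, "n": 4.37, "t50": 0.1}},
        {"family": "mono_exponential", "t_lo": 6.0, "t_hi": 12.0,
         "coefficients": {"amplitude": 1.619, "rate": 0.116}}
      ]
    },
    {
      "id": "milk_ph",
      "name": "Milk pH",
      "units": "pH",
      "cv": 0.03,
      "distribution": "normal_truncated",
      "segments": [
        {"family": "double_exponential", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"a1": 0.443, "k1": 13.07, "a2": 7.167, "k2": -0.0023}}
      ]
    },
    {
      "id": "milk_fat",
      "name": "Milk fat concentration",
      "units": "g/dL",
      "cv": 0.37,
      "distribution": "lognormal",
      "segments": [
        {"family": "polynomial", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"c0": 3.69, "c1": 0.04458627, "c2": 0.00063099}}
      ]
    },
    {
      "id": "milk_protein",
      "name": "Milk total protein",
      "units": "%",
      "cv": 0.23,
      "distribution": "lognormal",
      "segments": [
        {"family": "exp_decay_to_baseline", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"baseline": 1.219, "amplitude": 1.127, "rate": 5.058}}
      ]
    },
    {
      "id": "milk_water",
      "name": "Milk water content",
      "units": "%",
      "cv": 0.015,
      "distribution": "normal_truncated",
      "segments": [
        {"family": "constant", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"value": 87.5}}
      ]
    },
    {
      "id": "milk_intake",
      "name": "Daily infant milk intake per kg bodyweight",
      "units": "L/kg/day",
      "cv": 0.25,
      "distribution": "lognormal",
      "segments": [
        {"family": "hill", "t_lo": 0.0, "t_hi": 1.0,
         "coefficients": {"emax": 0.181, "n": 2.411, "t50": 0.114}},
        {"family": "exp_decay_to_baseline", "t_lo": 1.0, "t_hi": 12.0,
         "coefficients": {"baseline": 0.004, "amplitude": 0.204, "rate": 0.15}}
      ]
    },
    {
      "id": "haematocrit",
      "name": "Maternal haematocrit",
      "units": "%",
      "cv": 0.08,
      "distribution": "normal_truncated",
      "segments": [
        {"family": "offset_hill", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"baseline": 31.17, "plateau": 38.74, "n": 2.49, "t50": 0.133}}
      ]
    },
    {
      "id": "agp",
      "name": "Maternal alpha-1-acid glycoprotein",
      "units": "g/L",
      "cv": 0.24,
      "distribution": "lognormal",
      "segments": [
        {"family": "double_weibull", "t_lo": 0.0, "t_hi": 1.0,
         "coefficients": {"k1": 1.277, "k2": 6.749, "offset": 0.6}},
        {"family": "linear", "t_lo": 1.0, "t_hi": 12.0,
         "coefficients": {"intercept": 0.90, "slope": -0.016}}
      ]
    },
    {
      "id": "hsa",
      "name": "Maternal human serum albumin",
      "units": "g/L",
      "cv": 0.10,
      "distribution": "lognormal",
      "segments": [
        {"family": "logistic", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"baseline": 32.7, "span": 12.15, "rate": 7.16, "t_mid": 0.866}}
      ]
    },
    {
      "id": "breast_volume",
      "name": "Empty breast volume",
      "units": "L",
      "cv": 0.10,
      "distribution": "lognormal",
      "segments": [
        {"family": "linear", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"intercept": 1.549, "slope": -0.024}}
      ]
    },
    {
      "id": "plasma_volume",
      "name": "Maternal plasma volume",
      "units": "L",
      "cv": 0.13,
      "distribution": "lognormal",
      "segments": [
        {"family": "exp_decay_to_baseline", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"baseline": 2.67, "amplitude": 0.106, "rate": 2.017406150760383}}
      ]
    },
    {
      "id": "cardiac_output",
      "name": "Maternal cardiac output",
      "units": "L/h",
      "cv": 0.16,
      "distribution": "lognormal",
      "segments": [
        {"family": "double_exponential", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"a1": 98.8, "k1": 3.33, "a2": 304.4, "k2": 0.00096}}
      ]
    },
    {
      "id": "gfr",
      "name": "Maternal glomerular filtration rate",
      "units": "mL/min",
      "cv": 0.36,
      "distribution": "lognormal",
      "segments": [
        {"family": "polynomial", "t_lo": 0.0, "t_hi": 12.0,
         "coefficients": {"c0": 151.0285, "c1": -57.1898, "c2": 17.1856, "c3": -1.8479, "c4": 0.0661}}
      ]
    }
  ]
}
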