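{
  "WI-38": {
    "label": "WI-38",
    "k_N_per_Gy": 38.4,
    "a_per_h": 5.59e-3,
    "b_per_h": 8.17e-6,
    "a_plus_c_per_h": 0.371,
    "alpha0_per_Gy": 0.590,
    "beta0_per_Gy2": 1.63e-2,
    "gamma_Gy": 0.954,
    "sd": {
      "k_N_per_Gy": 1.70,
      "a_per_h": 1.20e-3,
      "b_per_h": 6.73e-6,
      "a_plus_c_per_h": 3.84e-2,
      "alpha0_per_Gy": 1.07e-1,
      "beta0_per_Gy2": 1.32e-2
    }
  },
  "HLEC": {
    "label": "HLEC",
    "k_N_per_Gy": 40.6,
    "a_per_h": 4.27e-3,
    "b_per_h": 6.58e-6,
    "a_plus_c_per_h": 0.309,
    "alpha0_per_Gy": 0.559,
    "beta0_per_Gy2": 1.75e-2,
    "gamma_Gy": 0.954,
    "sd": {
      "k_N_per_Gy": 2.63,
      "a_per_h": 1.07e-3,
      "b_per_h": 4.90e-6,
      "a_plus_c_per_h": 5.58e-2,
      "alpha0_per_Gy": 9.51e-2,
      "beta0_per_Gy2": 1.24e-2
    }
  }
}
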