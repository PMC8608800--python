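{
  "meta": {
    "species": "Xylonora atlantica",
    "T_ref_K": 293.15,
    "provenance": "primary parameters from the published abj-DEB entry; k_J, kappa_R, T_A, EH_h, d_V, w_E, mu_E are standard auxiliary values (EH_h calibrated to a 5.6-d hatching age at 4 degC)"
  },
  "kappa": 0.73,
  "pAm_b": 14.36,
  "v_b": 0.0053,
  "E_G": 2349.0,
  "p_M": 29.22,
  "k_J": 0.002,
  "kappa_R": 0.95,
  "EH_h": 1.3648357887327437e-05,
  "EH_b": 0.00104,
  "EH_j": 0.0203,
  "EH_p": 1.65,
  "T_A": 8000.0,
  "T_ref": 293.15,
  "delta_ME": 0.629,
  "delta_M": 0.599,
  "d_V": 0.09,
  "w_E": 23.9,
  "mu_E": 550000.0,
  "pAm_j": 38.77,
  "v_j": 0.0143
}
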