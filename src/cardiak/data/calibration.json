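{
  "alpha_um_s_per_ua_uf": 134.8652,
  "stim_threshold_ua_uf": 49.707,
  "gna_ms_uf": 5.37,
  "gkatp_ms_uf": 4.0,
  "s_ical": 2.0,
  "s_ina": 2.0,
  "s_inal": 3.0,
  "s_inaca": 1.2,
  "s_inak": 0.25,
  "s_lpc_na_per_um": 0.0167,
  "g_lpc_nal_per_um": 0.01,
  "stim_threshold_1d_ua_uf": 279.69,
  "kmnak0_mm": 0.3,
  "kadp_um": 25.0,
  "qadp": 6.0,
  "hnak": 2.61,
  "kmnakmax_mm": 11.73,
  "kmratio_ca": 0.35,
  "katp_km_scale": 17.0,
  "katp_h_scale": 4.3
}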