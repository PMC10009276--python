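{
 "description": "normoxic 1 Hz steady state (pre-paced limit cycle) for the calibrated parameter set; paced at twice the diastolic threshold",
 "bcl_ms": 1000.0,
 "state": [
  -87.29773009854836,
  7.330597589482271,
  7.330683125382017,
  140.37991721488868,
  140.37988677682154,
  8.327350462288252e-05,
  8.240836272185785e-05,
  1.5612489409672743,
  1.4992217205979808,
  0.0011037654185923928,
  0.7970208960196842,
  0.7965604846416668,
  0.00021520494531303885,
  0.47660812575680184,
  0.25059647782131617,
  0.0010497742153992677,
  0.9994955806481901,
  0.5816489616070807,
  0.0005349010817303531,
  0.9994956033681984,
  0.6324393435944804,
  2.764876672086432e-09,
  0.9999999889555038,
  0.9107313345488617,
  0.9999999889557301,
  0.9998107590656422,
  0.999973791368362,
  0.002450626724791594,
  0.9999999889460046,
  0.9999999889465955,
  9.006194805968216e-06,
  0.46413532028837595,
  0.27056947026769634,
  0.00020878031038384917,
  0.9969440795908632,
  2.465683362616757e-07,
  3.0796973855513896e-07,
  0.013440385648444853,
  5.397209936529412
 ]
}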