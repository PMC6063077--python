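# Species parameter set: Larix decidua (European larch, Alpine treeline)
name: Larix decidua
geometry:
  CA0: 308.0
  WA0: 39.0
  LWA0: 0.0
  CTD: 30.0
  WT0: 0.5
kinetics:
  vc: 0.39
  CAmax: 2989.0
  WTstar: 1.85
  vw: 11.26
  WAmax: 553.0
  mw: 124.0
  sw: 2.77
  vl: 10.77
  ml: 108.0
  sl: 0.56
sugar_curve:
  family: quadratic
  a: 2.78
  b: -0.53
  c: 1.83
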