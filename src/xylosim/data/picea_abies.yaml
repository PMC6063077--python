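# Species parameter set: Picea abies (Norway spruce, Alpine treeline)
name: Picea abies
geometry:
  CA0: 248.0
  WA0: 35.0
  LWA0: 0.0
  CTD: 27.0
  WT0: 0.5
kinetics:
  vc: 0.44
  CAmax: 2206.0
  WTstar: 1.02
  vw: 8.18
  WAmax: 1145.0
  mw: 503.0
  sw: 5.34
  vl: 8.23
  ml: 523.0
  sl: 5.44
sugar_curve:
  family: quadratic
  a: 1.46
  b: -0.10
  c: 1.81
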