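# Species parameter set: Picea mariana (black spruce, Quebec boreal forest)
name: Picea mariana
geometry:
  CA0: 362.0
  WA0: 43.0
  LWA0: 0.0
  CTD: 33.0
  WT0: 0.5
kinetics:
  vc: 0.41
  CAmax: 1402.0
  WTstar: 1.71
  vw: 11.43
  WAmax: 596.0
  mw: 193.0
  sw: 4.18
  vl: 12.96
  ml: 100.0
  sl: 0.45
sugar_curve:
  family: exponential
  a: 0.03
  b: 4.15
  c: 0.79
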