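# Species parameter set: Pinus cembra (stone pine, Alpine treeline)
name: Pinus cembra
geometry:
  CA0: 327.0     # initial cell area, um^2
  WA0: 41.0      # initial (primary) wall area, um^2
  LWA0: 0.0      # initial lignified area, um^2
  CTD: 31.0      # cell tangential diameter, um
  WT0: 0.5       # primary wall thickness, um
kinetics:
  vc: 0.39       # enlargement max rate, 1/d
  CAmax: 3180.0  # max cell area, um^2
  WTstar: 1.10   # wall-thickness threshold, um
  vw: 8.54       # wall deposition max rate, um^2/d
  WAmax: 915.0   # max wall area, um^2
  mw: 505.0      # deposition saturation scale (lumen area), um^2
  sw: 5.58       # deposition saturation exponent
  vl: 7.79       # lignification max rate, um^2/d
  ml: 515.0      # lignification saturation scale (lumen area), um^2
  sl: 5.63       # lignification saturation exponent
sugar_curve:
  family: quadratic
  a: 1.77
  b: -0.07
  c: 1.60
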