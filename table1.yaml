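# Canonical dimensionless parameter set of the model (zebrafish Her-oscillator
# based), plus a dimensional set that maps onto it exactly.
dimensionless:
  eta1: 0.76
  eta2: 0.008
  eta3: 0.02
  eta4: 0.01
dimensional:
  k1: 0.017131165956651616   # = 0.76*sqrt(125)/496: maps to eta1 = 0.76
  k2: 0.02
  k3: 1.0
  k4: 495.0
  k5: 1.0
  P0: 1.0
  X0: 1.0
  alpha: 124.0
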