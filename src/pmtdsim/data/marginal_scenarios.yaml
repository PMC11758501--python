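# Bundled marginal (covariate-averaged) toxicity probability scenarios.
# One row per scenario; the MTD is the dose whose marginal probability is
# closest to tau. Doses in mg.
doses: [1.0, 3.0, 5.0, 7.0, 9.0]
reference_dose: 5.0
tau: 0.25
scenarios:
  d1: [0.25, 0.39, 0.46, 0.51, 0.55]
  d2: [0.04, 0.24, 0.47, 0.64, 0.75]
  d3: [0.003, 0.07, 0.24, 0.45, 0.62]
  d4: [0.001, 0.03, 0.11, 0.25, 0.42]
  d5: [0.0, 0.001, 0.02, 0.09, 0.26]
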