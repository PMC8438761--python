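# SYNTHETIC weighted-SASA atom-type weight table, for tests and examples only.
# The published WSAS parameterisation's per-atom-type weights are not
# reproduced here; real analyses must supply their own calibrated table.
units: cal/(mol K)
k: 0.8
default_weight: 0.0
weights:
  C: 0.02
  N: -0.01
  O: -0.015
  S: 0.025
  H: 0.005
  P: 0.02
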