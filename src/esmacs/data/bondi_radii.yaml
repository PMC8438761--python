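# Bondi-style van der Waals element radii (Å) and default water probe.
# These are configuration, not asserted truth: override per project.
probe_radius: 1.4
radii:
  H: 1.20
  D: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  CL: 1.75
  BR: 1.85
  I: 1.98
  NA: 2.27
  K: 2.75
  MG: 1.73
  CA: 2.31
  ZN: 1.39
  FE: 2.05
  SE: 1.90
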