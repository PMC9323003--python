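# Asymptotic power to detect a prenatal maternal genetic effect explaining
# 1.5% of offspring phenotypic variance, at UK-Biobank-like group sizes.
# Run:  adoptsem power --config examples/ukb_like.yaml --out results/
params:
  gamma_m: 0.12247448713915890  # sqrt(0.015)
  beta_m: 0.0
  beta_p: 0.0
  beta_o: 0.0
  rho: 0.0
  phi: 1.0
  eps1_sq: 0.985   # unit total phenotypic variance
  eps2_sq: 0.985
sizes:
  G1: 1000     # biological parent-offspring trios
  G2: 4000     # biological mother-offspring pairs
  G3: 1800     # biological father-offspring pairs
  G4: 300000   # singletons raised by biological parents
  G5: 6000     # adopted singletons
  G7: 50       # biological mother - adopted offspring pairs
constraint: gamma_m
alpha: 0.05
seed: 1
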