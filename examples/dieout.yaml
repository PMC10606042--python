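# Sub-threshold scenario (R0 ~ 0.33): the infection is eradicated and the
# system relaxes to the disease-free state S_k = b/(b+d).
params:
  b: 0.4
  d: 0.01
  r: 0.02
  beta: 0.02
  p: 0.3
  gamma: 0.5
  delta: 0.1
  lambda: 0.02
  eta: 0.3
  mu: 0.7
degree_distribution:
  exponent: 3.0
  max_degree: 500
  normalization: renormalized
init:
  mode: uniform_seed
  I0: 0.01
integration:
  t_end: 3000.0
  n_report: 201
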