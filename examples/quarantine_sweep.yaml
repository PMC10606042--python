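# Sweep the quarantine rate delta above threshold: the endemic infection
# level decreases as quarantine strengthens.
params:
  b: 0.4
  d: 0.01
  r: 0.02
  beta: 0.4
  p: 0.3
  gamma: 0.5
  delta: 0.1
  lambda: 0.02
  eta: 0.3
  mu: 0.7
degree_distribution:
  exponent: 3.0
  max_degree: 500
init:
  mode: uniform_seed
  I0: 0.01
integration:
  t_end: 2000.0
  n_report: 101
sweep:
  parameter: delta
  values: [0.0, 0.1, 0.2, 0.4, 0.8]
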