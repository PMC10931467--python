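schema: 1
name: table1_baseline
note: >
  Baseline parameter table. Ranged parameters are pinned to tau=0.05 and
  alpha=0.4 and phi=0.45 (low end / midpoints of their reported ranges);
  override per run as needed.
params:
  Lambda: 0.5
  zeta: 0.35
  lam: 0.4
  tau: 0.05
  alpha: 0.4
  beta: 0.01
  chi: 0.25
  upsilon: 0.7
  sigma: 0.25
  omega: 0.8
  psi: 0.0027
  Phi: 0.7
  rho: 0.01
  phi: 0.45
initial_state: [100, 1, 5, 2, 0, 10]
h: 0.001
t_end: 500
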