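schema: 1
name: case2_r0_gt_1
note: >
  Supercritical reference scenario (R0 = 1.3372 > 1): addiction persists
  and the trajectory converges to the endemic equilibrium
  (4.3123, 0.5588, 0.1799, 0.1055, 0.2013, 1.0055).
extends: table1_baseline
params:
  Lambda: 0.60556
  chi: 0.26104
  phi: 0.89339
  sigma: 0.22874
  Phi: 0.80142
  beta: 0.010014
  tau: 0.095
  alpha: 0.47155
  psi: 0.002909
initial_state: [100, 1, 5, 2, 0, 10]
h: 0.001
t_end: 500
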