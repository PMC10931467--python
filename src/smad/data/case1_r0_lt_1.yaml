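schema: 1
name: case1_r0_lt_1
note: >
  Subthreshold reference scenario (R0 = 0.8684 < 1): addiction dies out
  and the trajectory converges to the addiction-free equilibrium
  (5, 0, 0, 0, 0, 0.5556).
extends: table1_baseline
params:
  tau: 0.09
  alpha: 0.5
  phi: 0.8
initial_state: [100, 1, 5, 2, 0, 10]
h: 0.001
t_end: 500
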