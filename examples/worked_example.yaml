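# Hot-flash severity trial planning scenario.
# Baseline severity X and its prescreen surrogate Z are N(5, 2^2) on the
# 0-10 severity scale with correlation 0.7; the treatment effect grows with
# baseline severity (negative interaction coefficient on a symptom outcome).
outcome:
  beta0: 0.0
  beta1: -0.2
  beta2: 1.0
  beta3: -0.25
  sigma: 2.5
screening:
  mu_x: 5.0
  sd_x: 2.0
  mu_z: 5.0
  sd_z: 2.0
  rho: 0.7
costs:
  c_trt: 700.0
  c_placebo: 700.0
  c_rec: 300.0
  c_scr: 200.0
  c_pre: 100.0
test:
  alpha: 0.05
  target_power: 0.90
  use_z_critical: true
currency: USD
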