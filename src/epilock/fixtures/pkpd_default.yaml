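parameters:
  f_ad: 0.1
  f_fb: 0.5
  k_act: 0.4
  k_bi: 0.4
  k_conv: 2.0
  k_dc: 0.35
  k_dm: 0.0866
  k_dp: 0.0289
  k_eb: 0.3
  k_ei: 0.2
  k_eic: 0.1
  k_ic: 1.0
  k_rep: 0.05
  k_tl: 1.0
  k_tx: 1.0
schedule:
  amount_mg_per_m2: 150.0
  interval_h: 24.0
  n_doses: 5
  reference_mg_per_m2: 150.0
  start_h: 24.0
schema: epilock/pkpd/1
units: rate constants in h^-1 (f_ad, f_fb dimensionless); dose in mg/m^2; times in
  hours; concentrations in model units (one reference dose = 1 blood unit)
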