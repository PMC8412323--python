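config:
  apportionment: per_destination
  dt_h: 1.0
  gate_mode: fraction
  gate_threshold: 0.5
  horizon_h: 144.0
  kill_base_per_day: 1.0
  kill_gain_per_o6mg: null
  kill_target_per_day: 2.2
  max_events_per_window: 1000000
  mgmt_kill_fraction: 0.2
  ode_dt_h: 0.02
  rescue: true
  rescue_threshold: 10
  saturation_o6mg: null
schema: epilock/hybrid/1
units: dt/horizon in hours; kill rates in day^-1
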