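lung:
  compliance: 1.5
  resistance: 40.0
  weight: 3.0
apparatus:
  mode: intubated
  tube_label: ETT-3.5
  rohrer_k1: 15.0
  rohrer_k2: 850.0
ventilator:
  mode: psv
  pressure_support: 10.0
  peep: 4.0
  bias_flow: 0.5
  trigger_deviation: 0.25
  insp_fraction: 0.45
  rise_time_constant: 0.05
  cycle_off_fraction: 0.3
  actuation_delay: 0.04
  exp_resistance: 180.0
effort:
  rate: 24.0
  tidal_volume_target: 30.0
  rise_fraction: 0.3
  hold_fraction: 0.0
  release_fraction: 0.3
  amplitude: 0.0
numerics:
  dt: 0.0005
  n_breaths: 10
  discard_breaths: 4
  vt_tolerance: 0.1
  noise_rel_sd: 0.0
  seed: null
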