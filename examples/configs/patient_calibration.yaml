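# Scan the cortico-thalamic feedback plane of the theta/alpha loop and
# select cells matching the patient locking targets.
seed: 0
populations:
  thalamus: {center_hz: 10.0, half_width_hz: 0.5, n: 1000}
  cortical:
    - {name: theta, center_hz: 6.0, half_width_hz: 0.5, n: 1000}
    - {name: alpha, center_hz: 10.0, half_width_hz: 0.5, n: 1000}
couplings:
  thal_to_cortex: [1.0, 0.6]
  cortex_to_thal: [2.0, 1.0]
stimulus: {intensity: 100.0, onset_ms: 0.0, duration_ms: 50.0}
integration: {dt_ms: 0.1, t_end_ms: 1600.0}
task:
  kind: calibrate
  target: patient
  top_k: 3
  scan:
    axis1: KC_theta
    axis2: KC_alpha
    range1: [9.3, 10.0, 0.05]
    range2: [3.3, 4.3, 0.05]
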