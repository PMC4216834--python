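# One-parameter sweep of the thalamus->cortex coupling at K_C = 1.2:
# origin stability, orbit branches, located Hopf and fold points.
seed: 0
populations:
  thalamus: {center_hz: 10.0, half_width_hz: 0.5, n: 1000}
  cortical:
    - {name: theta, center_hz: 6.0, half_width_hz: 0.5, n: 1000}
couplings:
  thal_to_cortex: [5.5]
  cortex_to_thal: [1.2]
stimulus: {intensity: 100.0, onset_ms: 0.0, duration_ms: 50.0}
integration: {dt_ms: 0.1, t_end_ms: 1100.0}
task:
  kind: bifurcate
  bifurcation: {parameter: k_thal_to_cortex, band: 0, k_min: 1.0, k_max: 16.0, k_step: 1.0}
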