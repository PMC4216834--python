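# Minimal loop at the ghost-transient operating point: phase reset,
# transient locking, finite-time desynchronisation.
seed: 1
populations:
  thalamus: {center_hz: 10.0, half_width_hz: 0.5, n: 1000}
  cortical:
    - {name: theta, center_hz: 6.0, half_width_hz: 0.5, n: 1000}
couplings:
  thal_to_cortex: [5.5]
  cortex_to_thal: [1.2]
stimulus: {intensity: 100.0, onset_ms: 0.0, duration_ms: 50.0}
integration: {dt_ms: 0.1, t_end_ms: 1600.0, store_every: 10}
task: {kind: simulate}
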