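{
  "n_steps": 150,
  "seed": 1,
  "mode": "tv",
  "scenario": {"scenario": "periodic", "period_steps": 50},
  "gp": {"T_t": 50.0},
  "protocol": {"step_duration_s": 24.0, "stim_window_s": 4.0, "baseline_window_s": 6.0}
}
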