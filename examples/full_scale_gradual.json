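{
  "n_steps": 3000,
  "seed": 1,
  "mode": "tv",
  "scenario": {"scenario": "gradual"},
  "gp": {"kernel_kind": "forgetting", "epsilon": 0.1}
}
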