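{
  "neck": {"region": "neck", "a2": 6.67e-05, "a1": 0.003, "a0": 0.213, "valid_age_range": [20, 75]},
  "shoulder": {"region": "shoulder", "a2": 3e-05, "a1": 0.0019, "a0": 0.3, "valid_age_range": [20, 75]},
  "elbow": {"region": "elbow", "a2": 0.0001767, "a1": 0.0047, "a0": 0.083, "valid_age_range": [20, 75]}
}
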