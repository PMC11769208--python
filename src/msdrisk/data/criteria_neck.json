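{
  "region": "neck",
  "rounding_mode": "table_match",
  "criteria": [
    {
      "name": "physical_readiness",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Low": 1.018, "Medium": 0.901, "High": 0.161}
    },
    {
      "name": "sex",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Male": 1.120, "Female": 0.930}
    },
    {
      "name": "technique_scenario",
      "weight_score": 1,
      "kind": "proportional",
      "levels": {"w/o Belt": 0.952, "w Belt": 1.024}
    },
    {"name": "amplitude", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "moment", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "cumulative_moment", "weight_score": 2, "kind": "parametric", "levels": {}}
  ],
  "notes": {
    "physical_readiness.High": "Published value 0.161 is an outlier versus every other likelihood (~0.9-1.1) and is plausibly a misprint for ~1.061; the published value is kept as the default."
  }
}
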