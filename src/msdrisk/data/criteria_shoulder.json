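{
  "region": "shoulder",
  "rounding_mode": "table_match",
  "criteria": [
    {
      "name": "physical_readiness",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Low": 1.009, "Medium": 0.997, "High": 1.030}
    },
    {
      "name": "sex",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Male": 1.016, "Female": 0.991}
    },
    {
      "name": "technique_scenario",
      "weight_score": 1,
      "kind": "proportional",
      "levels": {"w/o Belt": 0.919, "w Belt": 1.041}
    },
    {
      "name": "symmetry",
      "weight_score": 2,
      "kind": "proportional",
      "levels": {"Left": 1.009, "Right": 0.998}
    },
    {"name": "amplitude", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "moment", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "cumulative_moment", "weight_score": 2, "kind": "parametric", "levels": {}}
  ],
  "notes": {}
}
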