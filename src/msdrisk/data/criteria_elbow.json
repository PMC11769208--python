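{
  "region": "elbow",
  "rounding_mode": "display3",
  "criteria": [
    {
      "name": "physical_readiness",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Low": 1.008, "Medium": 0.998, "High": 1.029}
    },
    {
      "name": "sex",
      "weight_score": 1,
      "kind": "categorical",
      "levels": {"Male": 1.019, "Female": 0.989}
    },
    {
      "name": "technique_scenario",
      "weight_score": 1,
      "kind": "proportional",
      "levels": {"w/o Belt": 0.976, "w Belt": 1.017}
    },
    {
      "name": "symmetry",
      "weight_score": 2,
      "kind": "proportional",
      "levels": {"Left": 1.005, "Right": 0.999}
    },
    {"name": "amplitude", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "moment", "weight_score": 1, "kind": "parametric", "levels": {}},
    {"name": "cumulative_moment", "weight_score": 2, "kind": "parametric", "levels": {}}
  ],
  "notes": {
    "rounding": "The published display rounds every coefficient independently; the displayed weights sum to 0.999 and the residual is reported by the normalization check."
  }
}
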