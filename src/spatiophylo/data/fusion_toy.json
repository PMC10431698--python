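{
  "name": "fusion",
  "description": "Toy fusion definition: each feature asks whether a grammatical function is marked by phonologically bound material, and every feature forms its own function-group (the score is the plain mean of present indicators). Feature identifiers follow the GBxxx convention; derivational morphology (GB047-GB049) is excluded from scoring.",
  "groups": {
    "GB070": ["GB070"],
    "GB080": ["GB080"],
    "GB081": ["GB081"],
    "GB082": ["GB082"],
    "GB083": ["GB083"],
    "GB084": ["GB084"],
    "GB086": ["GB086"],
    "GB089": ["GB089"],
    "GB090": ["GB090"],
    "GB094": ["GB094"]
  },
  "excluded_features": ["GB047", "GB048", "GB049"]
}
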