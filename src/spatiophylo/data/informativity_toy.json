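{
  "name": "informativity",
  "description": "Toy informativity definition: function-groups join the bound and independent exponents of one grammatical distinction (e.g. plural marking by affix or by particle), and a group counts once if any member is present. Universally marked domains are excluded.",
  "groups": {
    "plural_marking": ["GB041", "GB042"],
    "definite_article": ["GB020", "GB021"],
    "past_tense": ["GB082", "GB085"],
    "inclusive_exclusive": ["GB028", "GB029"],
    "gender_agreement": ["GB030", "GB051"]
  },
  "excluded_features": ["GB107", "GB116"]
}
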