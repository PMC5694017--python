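{
  "contrasting_conjunctions": [
    "but",
    "whereas",
    "however",
    "although",
    "while",
    "but not"
  ],
  "similarity_conjunctions": [
    "and",
    "or",
    "as well as"
  ],
  "linking_phrases": [
    "binds to",
    "binds with",
    "interacts with",
    "interacted with",
    "associates with",
    "associated with",
    "as a result",
    "as"
  ],
  "negation_markers": [
    "not",
    "not with",
    "neither"
  ]
}
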