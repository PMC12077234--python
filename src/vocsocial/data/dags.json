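{
  "similarity": {
    "outcome": "similarity",
    "edges": [
      ["relatedness", "mate"],
      ["relatedness", "tolerance"],
      ["nest", "mate"],
      ["nest", "foraging"],
      ["nest", "tolerance"],
      ["mate", "tolerance"],
      ["mate", "similarity"],
      ["relatedness", "similarity"],
      ["foraging", "similarity"],
      ["nest", "similarity"],
      ["tolerance", "similarity"]
    ]
  },
  "diversity": {
    "outcome": "diversity",
    "edges": [
      ["age", "chamber_size"],
      ["sex", "chamber_size"],
      ["age", "tree_size"],
      ["sex", "tree_size"],
      ["nest", "tree_size"],
      ["chamber_size", "tree_size"],
      ["age", "nest"],
      ["nest", "network_position"],
      ["age", "network_position"],
      ["sex", "network_position"],
      ["tolerance", "network_position"],
      ["tree_size", "network_position"],
      ["age", "diversity"],
      ["sex", "diversity"],
      ["chamber_size", "diversity"],
      ["tree_size", "diversity"],
      ["nest", "diversity"],
      ["network_position", "diversity"],
      ["tolerance", "diversity"]
    ]
  },
  "information": {
    "outcome": "information",
    "edges": [
      ["age", "tree_size"],
      ["age", "degree"],
      ["tree_size", "degree"],
      ["age", "information"],
      ["tree_size", "information"],
      ["degree", "information"]
    ]
  }
}
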