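{
  "seed": 7,
  "outdir": "artifacts",
  "population": {"n_individuals": 60, "n_trees": 18},
  "observations": {"n_sessions": 40, "tolerance_rate": 1.2},
  "calls": {"mean_calls": 45, "trace_len": 80},
  "similarity_effect": 0.5,
  "sampler": {"chains": 4, "warmup": 600, "draws": 600, "dm_warmup": 2000, "dm_draws": 800},
  "effects": [
    {"outcome": "similarity", "exposure": "tolerance", "kind": "total"},
    {"outcome": "similarity", "exposure": "relatedness", "kind": "total"},
    {"outcome": "diversity", "exposure": "chamber_size", "kind": "total"},
    {"outcome": "diversity", "exposure": "age", "kind": "direct"},
    {"outcome": "entropy", "exposure": "sex", "kind": "direct"},
    {"outcome": "entropy", "exposure": "tree_size", "kind": "total"}
  ]
}
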