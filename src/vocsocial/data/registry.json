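[
  {"outcome": "similarity", "exposure": "mate", "covariates": ["relatedness", "foraging", "nest", "tolerance"], "dag": "similarity", "model": "S ~ M + R + F + N + T", "expectation": "more similar"},
  {"outcome": "similarity", "exposure": "foraging", "covariates": ["mate", "relatedness", "nest", "tolerance"], "dag": "similarity", "model": "S ~ M + R + F + N + T", "expectation": "more similar"},
  {"outcome": "similarity", "exposure": "nest", "covariates": ["mate", "relatedness", "foraging", "tolerance"], "dag": "similarity", "model": "S ~ M + R + F + N + T", "expectation": "more similar"},
  {"outcome": "similarity", "exposure": "tolerance", "covariates": ["mate", "relatedness", "foraging", "nest"], "dag": "similarity", "model": "S ~ M + R + F + N + T", "expectation": "more similar"},
  {"outcome": "similarity", "exposure": "relatedness", "covariates": ["mate", "tolerance"], "dag": "similarity", "model": "S ~ M + R + T", "expectation": "more similar"},
  {"outcome": "diversity", "exposure": "network_position", "covariates": ["nest", "age", "sex", "tolerance", "tree_size"], "dag": "diversity", "model": "D ~ N + A + Se + T + Tr", "expectation": "more diverse"},
  {"outcome": "diversity", "exposure": "age", "covariates": ["nest", "chamber_size", "sex"], "dag": "diversity", "model": "D ~ A + N + C + Se", "expectation": "less diverse"},
  {"outcome": "diversity", "exposure": "sex", "covariates": ["nest", "age", "chamber_size", "tree_size"], "dag": "diversity", "model": "D ~ N + A + Se + C + Tr", "expectation": "none"},
  {"outcome": "diversity", "exposure": "chamber_size", "covariates": ["age", "sex"], "dag": "diversity", "model": "D ~ C + A + Se", "expectation": "more diverse"},
  {"outcome": "diversity", "exposure": "tree_size", "covariates": ["nest", "age", "sex", "chamber_size"], "dag": "diversity", "model": "D ~ N + A + Se + C + Tr", "expectation": "more diverse"},
  {"outcome": "entropy", "exposure": "network_position", "covariates": ["nest", "age", "sex", "tolerance", "tree_size"], "dag": "diversity", "model": "E ~ N + A + Se + T + Tr", "expectation": "more diverse"},
  {"outcome": "entropy", "exposure": "age", "covariates": ["nest", "chamber_size", "sex"], "dag": "diversity", "model": "E ~ A + N + C + Se", "expectation": "less diverse"},
  {"outcome": "entropy", "exposure": "sex", "covariates": ["nest", "age", "chamber_size", "tree_size"], "dag": "diversity", "model": "E ~ N + A + Se + C + Tr", "expectation": "none"},
  {"outcome": "entropy", "exposure": "chamber_size", "covariates": ["age", "sex"], "dag": "diversity", "model": "E ~ C + A + Se", "expectation": "more diverse"},
  {"outcome": "entropy", "exposure": "tree_size", "covariates": ["nest", "age", "sex", "chamber_size"], "dag": "diversity", "model": "E ~ N + A + Se + C + Tr", "expectation": "more diverse"},
  {"outcome": "information", "exposure": "degree", "covariates": ["age", "tree_size"], "dag": "information", "model": "I ~ De + A + Tr", "expectation": "more information"},
  {"outcome": "information", "exposure": "tree_size", "covariates": ["degree", "age"], "dag": "information", "model": "I ~ De + A + Tr", "expectation": "more information"},
  {"outcome": "information", "exposure": "age", "covariates": ["degree", "tree_size"], "dag": "information", "model": "I ~ De + A + Tr", "expectation": "none"}
]
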