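# vocsocial

Bayesian analysis of how fine-scale social structure shapes vocal
complexity in colonial parrots.

Colonial-nesting parrots such as the monk parakeet (*Myiopsitta
monachus*) live in layered societies — breeding pairs share nest
chambers, chambers aggregate into stick-nest trees, and birds forage in
fission–fusion flocks — while producing a flexible, individually variable
contact call within a repertoire of 11 call types. The social complexity
hypothesis predicts that individuals embedded in larger or denser social
worlds should express more complex vocalizations. Testing this at the
*individual* level requires combining multilayer social networks with
several vocal measures, each with its own uncertainty. `vocsocial`
packages that whole analysis as tested, reusable code, exercisable end to
end on synthetic colonies with known ground truth:

- **networks** — five social layers (foraging with simple-ratio-index
  weights under gambit of the group, mate, affiliative, aggression,
  normalised nest distance), node metrics (degree, betweenness,
  eigenvector centrality) and multiplex *degree versatility*;
- **acoustics** — dynamic-time-warping distances between F0 traces and
  amplitude-modulation peak counts (information content, prominence
  threshold `min_height = 30`);
- **models** — hierarchical Bayesian decompositions of acoustic distance
  (statsmodels-style Model → `fit()` → Results):

  | model | measure | core structure |
  |---|---|---|
  | `DyadicDistanceModel` | similarity per dyad | `mu = alpha_dyad + alpha_rec[i] + alpha_rec[j]`, `alpha_dyad ~ N(alpha_bar, sigma_dyad)`, `sigma* ~ Exp(2)` |
  | `WithinIndividualDistanceModel` | diversity per bird | `mu = alpha_ind + alpha_same_rec + alpha_rec_pair + alpha_call_i + alpha_call_j`, `sigma ~ Exp(5)`, group sds `~ Exp(3)` |
  | `MeasurementErrorRegression` | stage-2 effects | `est_mean ~ N(z, est_sd)`, `z ~ N(a + X beta [+ u_i + u_j], sigma)` |
  | `InformationContentModel` | AM-peak counts | individual varying intercepts; sqrt-normal or Poisson |
  | `DirichletMultinomialModel` | repertoire composition | `x_i ~ Multinomial(p_i)`, `p_i ~ Dirichlet(theta * pi_i)`, `s_i = exp(log alpha + beta' A_i)` |

- **effects** — total vs direct effects via the back-door criterion on
  shipped DAGs, with posterior uncertainty from stage 1 propagated
  through a measurement-error likelihood and 89% posterior intervals
  throughout;
- **repertoire** — Shannon entropy of call-type use (≥30-call inclusion
  rule) and female-minus-male composition contrasts per call type;
- **synthdata** — a full synthetic-colony generator (individuals, nests,
  sightings, interactions, relatedness, calls with F0 traces) with every
  true effect size recorded for recovery testing;
- **pipeline / CLI** — `vocsocial run --config cfg.json --seed 7` drives
  all stages deterministically and writes delimited-text artifacts plus a
  JSON report.

Inference is blocked Gibbs sampling (conjugate normal updates, slice
sampling for scales, interweaving for weakly identified variance
components) for the normal hierarchical models and an affine-invariant
ensemble sampler for the marginalised Dirichlet-multinomial, with
split-Rhat/ESS diagnostics via arviz and a Rhat < 1.01 convergence gate
that warns rather than silently passing.

## Worked example

Simulate between-individual distance observations from the dyadic model's
own generative process (150 dyads × 8 observations; true
`sigma_dyad = 0.4`, `sigma_rec = 0.1`, `sigma = 0.2`), fit, and summarise:

```python
from vocsocial.synthdata import simulate_dyadic_distance_data
from vocsocial import DyadicDistanceModel, SamplerConfig

obs, truth = simulate_dyadic_distance_data(seed=11, n_dyads=150, obs_per_dyad=8,
                                           sigma_dyad=0.4, sigma_rec=0.1, sigma=0.2)
model = DyadicDistanceModel(obs)
results = model.fit(SamplerConfig(chains=4, warmup=1000, draws=1000, seed=5))
print(results.hyper_estimates("original").round(3).to_string(index=False))
print(results.dyad_estimates().head(3).round(3).to_string(index=False))
```

```
 parameter  mean    sd  pi89_low  pi89_high  rhat  ess_bulk
 alpha_bar 1.023 0.037     0.964      1.083 1.002   649.041
     sigma 0.199 0.005     0.192      0.206 1.001  2929.695
sigma_dyad 0.388 0.023     0.352      0.427 1.001  3302.530
 sigma_rec 0.088 0.009     0.075      0.103 1.003  1578.804
unit_id  mean    sd  pi89_low  pi89_high  rhat
  D0000 0.938 0.074     0.819      1.056 1.001
  D0001 1.732 0.075     1.611      1.851 1.002
  D0002 1.416 0.074     1.296      1.535 1.000
```

All three generating scale parameters sit inside their 89% posterior
intervals (`sigma_dyad`: truth 0.4 in [0.352, 0.427]); the per-dyad rows
(`dyad_estimates`) are the similarity levels whose posterior mean and sd
feed the stage-2 effect regressions as measurements with error.

The same pattern runs end to end from a config:

```bash
vocsocial run --config examples/colony.json --seed 7 --out artifacts/
vocsocial report --out artifacts/
```

which prints per-fit worst Rhat values and a tidy effect table (outcome,
exposure, total/direct, posterior mean and 89% interval, n) and renders a
forest plot.

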