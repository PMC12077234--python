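# Methods

`vocsocial` implements a simulation-testable analysis of how fine-scale
social structure relates to vocal complexity in a colonial, vocally
flexible parrot (the motivating system is the monk parakeet,
*Myiopsitta monachus*, nesting communally in city parks). This note
documents the models, the priors, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Social networks

Five layers are built over the marked population:

- **foraging** — gambit of the group: all members of an observed foraging
  group are taken to associate pairwise. Edges are weighted with the
  simple ratio index `SRI = x / (x + yA + yB + yAB)`, where `x` counts
  sampling sessions with the pair together, `yA`/`yB` sessions with only
  one of them seen, and `yAB` sessions with both seen but apart. Within a
  session a pair is counted together at most once. A dyad never co-sighted
  has *no* edge (an unsampled dyad is missing, not zero).
- **mate** — binary: shared nest entry (chamber) or an allopreening or
  explicit mate observation.
- **affiliative** — binary: any close-tolerance or allopreening event.
- **aggression** — binary, direction ignored.
- **nest distance** — planar Euclidean distance between assigned nest
  entries, normalised by the maximum observed distance (so the most
  separated dyad scores 1); entries in the same tree score exactly 0.

Node metrics: unweighted degree, betweenness (unnormalised shortest-path
counts with fractional credit on ties) and eigenvector centrality
(computed per connected component, scaled to a component maximum of 1;
isolated nodes score 0), all on the binarised foraging graph; *degree
versatility* sums unweighted degree across the four-layer multiplex
network (the nest layer is excluded as nearly collinear with the mate
layer); chamber and tree group sizes count occupants including the focal
bird. The network layers use binary graphs for centralities because the
association indices are sampling-effort-dependent; this is a package
design choice where the field convention varies.

Individuals observed at multiple entries are expected to be pre-assigned
to their modal entry upstream; the generator assigns each bird a single
entry directly.

## Acoustic distance and information content

Calls are represented by smoothed fundamental-frequency (F0) traces.
Pairwise acoustic distance is dynamic time warping with absolute local
cost, the symmetric step pattern (steps ↓, →, ↘), and the minimal
cumulative cost divided by the summed trace lengths. Traces are
mean-centred first, making the distance invariant to a constant pitch
offset; window constraints and smoothing are deliberately not imposed and
the centring is exposed as an argument. DTW is verified against an
exhaustive warping-path enumeration for short traces.

Information content of a call is the number of amplitude-modulation
peaks: local maxima whose prominence (height above the higher of the two
flanking troughs) is at least `min_height = 30`, counted with
`scipy.signal.find_peaks`. The loud-call subset used for this analysis is
selected by a flag on the call table when present, not re-derived
acoustically.

## Stage 1: hierarchical distance models

Distances are z-scored internally (the transform is stored and inverted
on export) so the priors below are weakly informative on the model scale.

**Between-individual (similarity)**: for each cross-individual call pair,

    distance ~ normal(mu, sigma)
    mu = alpha_dyad + alpha_rec[i] + alpha_rec[j]
    alpha_dyad ~ normal(alpha_bar, sigma_dyad);  alpha_bar ~ normal(0, 0.5)
    alpha_rec ~ normal(0, sigma_rec)
    sigma, sigma_dyad, sigma_rec ~ exponential(2)

`alpha_dyad` is the average acoustic distance within a dyad — the
similarity measure (higher = less similar). Recording offsets control for
repeated comparisons of the same recordings; each recording has one
offset and both recordings of a pair contribute additively. (A single
recording term could also be read as one offset per recording *pair*; the
additive two-term form was chosen because it matches the between-model's
role of the per-recording effect and nests the pair interpretation.)

**Within-individual (diversity)**: for each same-individual call pair,

    mu = alpha_ind + alpha_same_rec + alpha_rec_pair + alpha_call_i + alpha_call_j
    alpha_ind ~ normal(alpha_bar, sigma_ind);  alpha_bar ~ normal(0, 0.25)
    alpha_rec_pair ~ normal(0, sigma_rec_pair);  alpha_call ~ normal(0, sigma_call)
    sigma ~ exponential(5);  sigma_ind, sigma_rec_pair, sigma_call ~ exponential(3)

`alpha_ind` is the per-individual contact-call diversity.
`alpha_same_rec` is a single scalar offset applied when both calls come
from one recording, with prior normal(0, 0.5) (its prior is not otherwise
pinned down; a scalar keeps it identifiable next to the recording-pair
offsets). In the fully degenerate design where every call shares one
recording, `alpha_same_rec` and `alpha_rec_pair` are jointly
unidentifiable; the priors keep the posterior proper and the fit reports
normally.

**Sampling.** These are normal hierarchical models, so they are sampled
with a blocked Gibbs sampler written for this package: conjugate normal
updates for all location parameters (recording offsets jointly via their
multivariate-normal conditional using a precomputed incidence Gram
matrix; call offsets in graph-coloured blocks so that no two calls in one
update share an observation), stepping-out slice sampling for the scale
hyperparameters under their exponential priors, and
ancillarity–sufficiency interweaving (centred ↔ non-centred) updates for
`sigma_ind`/`alpha_bar`, which otherwise mix slowly when the variance
component is small. Defaults: 4 chains, 1000 warmup + 1000 retained
iterations, fixed per-chain seeds. Convergence is gated on split-Rhat <
1.01 for hyperparameters; a violation raises a `ConvergenceWarning`
rather than silently passing. Posterior summaries use equal-tailed 89%
intervals throughout.

Per-unit posterior means and standard deviations are exported on the
original distance scale for stage 2.

## Stage 2: effect models with measurement error

Exported summaries are treated as noisy measurements of a latent truth:

    est_mean_k ~ normal(z_k, est_sd_k)
    z_k ~ normal(intercept + x_k' beta [+ u_i + u_j], sigma_resid)

Dyadic outcomes get multi-membership varying intercepts `u` for the two
members of each dyad. Continuous predictors and the outcome are z-scored
internally; slope priors are normal(0, 0.5), intercept normal(0, 0.5)
(normal(1, 1) for entropy outcomes, which live near log K), and
exponential(2) priors on the scales — the stage-2 priors are package
defaults in the spirit of the stage-1 models, since no stricter
convention exists for them. Setting `est_sd = 0` pins the latent values
and reproduces an ordinary regression, which is used as a limiting-case
cross-check in the tests. Repertoire entropy is a computed (not
estimated) quantity, so its regressions run with `est_sd = 0`. Analyses
are complete-case per model.

Information content is modelled at the call level with individual varying
intercepts; the default likelihood is normal on square-root counts (a
variance-stabilising choice that keeps the model conjugate), with a
log-link Poisson alternative behind a config switch (sampled by
slice-within-Gibbs for coefficients and adaptive Metropolis for the
intercepts). The between-individual intercept s.d. `sigma_ind` is
reported alongside the slopes.

## Total vs direct effects

Candidate drivers are entangled (age → chamber size, nest location →
network position, ...), so each effect is estimated under an explicit
DAG, shipped as JSON edge lists. For an exposure X and outcome Y:

- **total** effect: adjust for X's parents (always a valid back-door
  set); verified in tests by d-separation after removing X's outgoing
  edges.
- **direct** effect: additionally condition on the mediators on X → Y
  paths, plus the mediators' parents (conditioning on a mediator opens
  back-door paths through them; a mediator's parent is either itself a
  mediator or a non-descendant of X, so this closure is safe).

The shipped registry lists the published model specification per
exposure. The information-content DAG reproduces all its registry rows
exactly from this algorithm. On the diversity DAG the chamber-size,
tree-size and network-position rows are reproduced exactly; the
registry's age and sex rows include sex (respectively omit network
position/tolerance) as precision covariates relative to the strict
back-door sets — the registry preserves the published sets verbatim and
documents the difference here. The abstract `network_position` node maps
to a concrete metric (degree by default) when formulas are built.

## Repertoire diversity and composition

Per-individual call-type counts over the 11 described types give the
repertoire; Shannon entropy `-sum p_i log p_i` (natural log, base
configurable; zero counts contribute 0) is the diversity measure.
Individuals with fewer than 30 vocalizations are excluded; the two
rarest types (*frill*, *other tonal*) are dropped from the composition
model, leaving 9 types.

Composition is a Dirichlet-multinomial:

    x_i ~ multinomial(p_i);  p_i ~ dirichlet(pi_i * theta)
    pi_i = s_i / sum(s_i);  s_i = exp(log(alpha) + beta' A_i)
    theta ~ exponential(0.2)
    alpha ~ dirichlet(5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    beta ~ normal(0, 0.5)

`theta` controls how tightly individuals concentrate at their predicted
proportions; the asymmetric Dirichlet prior encodes that the first type
(contact call) dominates. Sex enters as a 0/1 column of A with its own
per-type `beta` row; the reported sex contrast is the posterior of
`pi(F) - pi(M)` per type with other covariates at their means (these
contrasts sum to 0 by the simplex constraint). The per-individual `p_i`
are marginalised analytically (the compound is the Dirichlet-multinomial
distribution), leaving ~20–30 free parameters that are sampled with
emcee's affine-invariant ensemble (differential-evolution moves), with
`alpha` handled by an additive log-ratio transform whose Jacobian
combines with the Dirichlet prior to the density `prod alpha_k^{c_k}`.
Walkers are treated as chains for split-Rhat, which is conservative for
an ensemble; prior-only sampling reproduces the analytic Dirichlet mean
(E[alpha_1] = 5/9) to Monte-Carlo accuracy, validating the transform.

## Synthetic-data generator

The generator emulates the six inputs with study-scale defaults: ~150
marked birds, chambers of 1–4 (pairs most common), trees of up to 20,
park extent giving nest distances up to ~966 m, mean age 1200 days
(between the two field-season means), balanced sexes with log-normal
ages, ~8% of birds never assigned to a nest, tens of calls per bird in
recordings of ~8 calls, and contact-call-dominated type proportions.
Call types are drawn from exactly the Dirichlet-multinomial model above,
so the composition fit is a self-recovery of its own generator.

Acoustic space is a 3-D latent embedding per call: individual centroids
(between-individual structure), within-individual scatter whose log-scale
can depend on covariates, and an optional dyad-level push along supplied
edges (a positive effect moves connected individuals apart — less similar
calls). F0 traces are sums of sinusoids weighted by the embedding, so DTW
distance is monotone in embedding distance; AM "bumps" with
Poisson-distributed counts (covariate-dependent log-mean) carry the
information-content structure. The distributional form of
within-individual variation is not constrained by any convention;
isotropic Gaussian scatter was chosen as the simplest smooth unimodal
option and is documented in the config.

What the generator does **not** emulate: real DTW distances are bounded
and heteroscedastic in ways the embedding model is not; observation
effort is uniform (no weather/observer gaps); relatedness comes from a
configured pedigree, not marker data; there is no temporal drift in
calls, no audio, and no spatial movement. Passing recovery tests
therefore show that the estimators are correct and calibrated *under the
assumed data-generating process*, not that field data meet those
assumptions.

Direct model-level generators (`simulate_dyadic_distance_data`,
`simulate_within_distance_data`, `simulate_measured_outcomes`,
`simulate_repertoire_counts`) draw from the fitted models' own generative
processes for clean simulation-based calibration.

## Numerical choices and problem sizes

- Distances, outcomes and continuous predictors are z-scored inside the
  models; every transform is stored and inverted on export, and 0/1
  columns are never rescaled.
- All randomness flows through `numpy.random.Generator` seeded from the
  config; chains derive per-chain streams from (seed, chain). Two runs
  with one config are byte-identical.
- The O(n²) between-individual pair explosion is bounded by a per-dyad
  cap (default 3 pairs per dyad in the pipeline; unlimited in the
  library functions).
- Calibration suites run at 150 dyads × 8 observations, 60 individuals ×
  15 calls, n = 80 stage-2 units with 20 replicates (100 for null
  coverage), sizes at which the reference coverage behaviour is stable
  while a full run of the test suite and acceptance script completes on
  one CPU in well under an hour.
- Degenerate inputs: all-identical distances (scale collapses to a unit
  transform; variance components shrink toward 0), single shared
  recording (priors dominate, fit proper), empty event tables (empty
  layers, warning not error), all-zero call types (dropped with warning).

## Known limitations

- The Gibbs sampler covers the normal-likelihood models only; swapping in
  robust likelihoods would require a different kernel.
- Split-Rhat on ensemble walkers (composition model) is conservative;
  very small runs will warn even when sign inference is already stable.
- The entropy regression ignores sampling noise in entropy itself
  (matching the upstream convention of treating entropy as observed); a
  bootstrap `est_sd` would be a natural extension.
- Direct-effect adjustment uses the parent/mediator closure rather than
  full optimal-adjustment search; for graphs where a mediator's parent is
  a collider of other conditioned variables this can over-adjust. The
  shipped DAGs do not hit this case (verified by d-separation in tests).
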