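"""Synthetic colony generator with recorded ground truth.

Emulates the six inputs of the analysis pipeline for a colonial parrot
population: individuals (with sex, age and nest assignment), nest-site
coordinates, foraging sightings, typed dyadic interactions, a relatedness
matrix, and call records with fundamental-frequency traces. Every
operation is a pure function of (inputs, seed), and the true effect sizes
used for generation are returned in a :class:`GroundTruth` record so that
downstream model fits can be tested for parameter recovery.

Study-scale defaults mirror the field situation the pipeline targets: a
colony of ~150 marked birds, nest chambers of 1-4 birds, nesting trees of
up to 20, nest-to-nest distances spanning up to roughly a kilometre, 11
call types dominated by the contact call, and tens of calls per individual
spread over multi-call recordings.

Acoustic space is a low-dimensional latent embedding per call: each
individual has a centroid, each call scatters around it, and F0 traces are
smooth sums of sinusoids parameterised by the embedding, so that DTW
distance between traces is monotone in embedding distance. Optional
"bumps" superimposed on the trace carry the amplitude-modulation peak
structure used by the information-content analysis.
"""

from __future__ import annotations

import itertools
import json
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from vocsocial.repertoire import CALL_TYPES

__all__ = [
    "PopulationConfig",
    "ObservationConfig",
    "CallConfig",
    "GroundTruth",
    "simulate_population",
    "simulate_social_observations",
    "simulate_relatedness",
    "simulate_calls",
    "simulate_repertoire_counts",
    "simulate_dyadic_distance_data",
    "simulate_within_distance_data",
    "simulate_measured_outcomes",
    "simulate_dyadic_measured_outcomes",
    "write_tables",
]


class ConfigError(ValueError):
    """Infeasible or invalid generator configuration."""


class PopulationConfig(BaseModel):
    """Colony layout: individuals, chambers, trees, demography."""

    n_individuals: int = Field(150, ge=1)
    n_trees: int = Field(30, ge=1)
    #: probability of a chamber housing 1..4 birds (pairs dominate)
    chamber_size_probs: tuple[float, ...] = (0.25, 0.45, 0.2, 0.1)
    max_tree_size: int = Field(20, ge=1, le=20)
    female_prob: float = Field(0.5, ge=0.0, le=1.0)
    #: mean age in days (between the two field-season means)
    age_mean_days: float = Field(1200.0, gt=0)
    age_sigma_log: float = Field(0.9, gt=0)
    #: fraction of marked birds never assigned to a nest entry
    unassigned_prob: float = Field(0.08, ge=0.0, le=1.0)
    #: park side length; the diagonal then spans ~966 m
    park_extent_m: float = Field(683.0, gt=0)

    @field_validator("chamber_size_probs")
    @classmethod
    def _simplex_max4(cls, v):
        if len(v) > 4 or len(v) == 0:
            raise ValueError("chamber sizes are capped at 4")
        if any(p < 0 for p in v) or not np.isclose(sum(v), 1.0):
            raise ValueError("chamber_size_probs must be a probability vector")
        return tuple(v)


class ObservationConfig(BaseModel):
    """Sampling effort and per-layer interaction rates."""

    n_sessions: int = Field(60, ge=0)
    groups_per_session: int = Field(4, ge=1)
    mean_group_size: float = Field(5.0, ge=1.0)
    #: how strongly foraging groups aggregate around nest trees
    tree_assortativity: float = Field(4.0, ge=0.0)
    allopreen_rate: float = Field(0.5, ge=0.0)
    allopreen_within_entry_prob: float = Field(0.95, ge=0.0, le=1.0)
    tolerance_rate: float = Field(1.0, ge=0.0)
    tolerance_within_tree_prob: float = Field(0.6, ge=0.0, le=1.0)
    aggression_rate: float = Field(0.5, ge=0.0)
    mate_obs_rate: float = Field(0.0, ge=0.0)


class CallConfig(BaseModel):
    """Generative model for call types, embeddings and F0 traces."""

    mean_calls: float = Field(40.0, gt=0)
    min_calls_per_individual: int = Field(3, ge=1)
    calls_per_recording: int = Field(8, ge=1)
    #: average call-type proportions (contact call dominates)
    alpha: tuple[float, ...] = (0.55, 0.10, 0.06, 0.05, 0.05, 0.05, 0.04, 0.04, 0.03, 0.02, 0.01)
    #: per-type effect of standardised age on log-proportions
    beta_age: tuple[float, ...] = tuple([0.0] * 11)
    #: per-type additive effect for females on log-proportions
    beta_sex: tuple[float, ...] = tuple([0.0] * 11)
    #: Dirichlet concentration controlling between-individual dispersion
    theta: float = Field(15.0, gt=0)
    embed_dim: int = Field(3, ge=1)
    sigma_between: float = Field(1.0, gt=0)
    #: baseline within-individual embedding spread
    sigma_within: float = Field(0.4, gt=0)
    #: covariate effects on log within-individual spread, e.g. {"age": 0.3}
    gamma_within: dict[str, float] = Field(default_factory=dict)
    trace_len: int = Field(120, ge=8)
    trace_step_s: float = Field(0.0025, gt=0)
    f0_base_hz: float = Field(1500.0, gt=0)
    f0_scale_hz: float = Field(250.0, gt=0)
    #: amplitude of AM bumps; prominence comfortably above the threshold
    bump_height_hz: float = Field(60.0, ge=0.0)
    mean_peaks: float = Field(4.0, ge=0.0)
    #: covariate effects on log mean AM-peak count, e.g. {"tree_size": 0.4}
    peak_slopes: dict[str, float] = Field(default_factory=dict)

    @field_validator("alpha")
    @classmethod
    def _simplex(cls, v):
        if any(a < 0 for a in v) or not np.isclose(sum(v), 1.0):
            raise ValueError("alpha must be a simplex (nonnegative, sums to 1)")
        return tuple(v)


class GroundTruth(BaseModel):
    """True parameter values used by the generator, for recovery tests."""

    seed: int
    sigma_between: float
    sigma_within: float
    gamma_within: dict[str, float] = {}
    alpha: tuple[float, ...] = ()
    beta_age: tuple[float, ...] = ()
    beta_sex: tuple[float, ...] = ()
    theta: float = 1.0
    similarity_effect: float = 0.0
    mean_peaks: float = 0.0
    peak_slopes: dict[str, float] = {}

    def slope(self, outcome: str, predictor: str) -> float:
        """Look up a simulated effect by (outcome, predictor) name."""
        table = {
            ("diversity", k): v for k, v in self.gamma_within.items()
        }
        table.update({("information", k): v for k, v in self.peak_slopes.items()})
        table[("similarity", "tolerance")] = self.similarity_effect
        try:
            return table[(outcome, predictor)]
        except KeyError:
            raise KeyError(f"no simulated effect for ({outcome}, {predictor})") from None

    def to_json(self, path):
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))


# ---------------------------------------------------------------------------
# population & nests
# ---------------------------------------------------------------------------

def simulate_population(config: PopulationConfig, seed: int):
    """Simulate individuals and nest sites.

    Returns
    -------
    (individuals, nest_sites) : DataFrames
        ``individuals``: id, sex, age_days, tree_id, entry_id (missing for
        unassigned birds). ``nest_sites``: tree_id, nest_id, entry_id, x, y
        (entries in the same tree share coordinates up to ~1 m jitter).
    """
    rng = np.random.default_rng(seed)
    n = config.n_individuals
    capacity = config.n_trees * config.max_tree_size
    if n > capacity and config.unassigned_prob == 0.0:
        raise ConfigError(
            f"{n} individuals cannot all nest in {config.n_trees} trees of <= {config.max_tree_size}"
        )

    ids = [f"B{i:04d}" for i in range(1, n + 1)]
    sex = np.where(rng.uniform(size=n) < config.female_prob, "F", "M")
    mu = np.log(config.age_mean_days) - config.age_sigma_log**2 / 2.0
    age = np.round(rng.lognormal(mu, config.age_sigma_log, size=n)).astype(int)
    age = np.maximum(age, 30)

    assigned_mask = rng.uniform(size=n) >= config.unassigned_prob
    assigned = [i for i in range(n) if assigned_mask[i]]
    if len(assigned) > capacity:
        raise ConfigError(
            f"{len(assigned)} assigned individuals exceed nesting capacity {capacity}"
        )

    # partition assigned birds into chambers of 1-4
    sizes = []
    remaining = len(assigned)
    probs = np.asarray(config.chamber_size_probs)
    support = np.arange(1, len(probs) + 1)
    while remaining > 0:
        s = int(rng.choice(support, p=probs))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s

    # pack chambers into trees without exceeding the tree cap
    order = rng.permutation(len(sizes))
    tree_load = np.zeros(config.n_trees, dtype=int)
    tree_of_chamber = np.full(len(sizes), -1)
    for ci in order:
        s = sizes[ci]
        open_trees = np.flatnonzero(tree_load + s <= config.max_tree_size)
        if open_trees.size == 0:
            raise ConfigError("chambers cannot be packed within the tree-size cap")
        t = int(rng.choice(open_trees))
        tree_of_chamber[ci] = t
        tree_load[t] += s

    tree_xy = rng.uniform(0, config.park_extent_m, size=(config.n_trees, 2))
    nest_rows = []
    entry_of_chamber = []
    per_tree_counter: dict[int, int] = {}
    for ci, t in enumerate(tree_of_chamber):
        k = per_tree_counter.get(t, 0) + 1
        per_tree_counter[t] = k
        entry_id = f"T{t + 1:03d}E{k}"
        jitter = rng.normal(0.0, 0.5, size=2)
        nest_rows.append(
            {
                "tree_id": f"T{t + 1:03d}",
                "nest_id": f"T{t + 1:03d}N{k}",
                "entry_id": entry_id,
                "x": tree_xy[t, 0] + jitter[0],
                "y": tree_xy[t, 1] + jitter[1],
            }
        )
        entry_of_chamber.append((entry_id, f"T{t + 1:03d}"))

    tree_col = [pd.NA] * n
    entry_col = [pd.NA] * n
    pool = list(assigned)
    rng.shuffle(pool)
    pos = 0
    for ci, s in enumerate(sizes):
        entry_id, tree_id = entry_of_chamber[ci]
        for i in pool[pos : pos + s]:
            tree_col[i] = tree_id
            entry_col[i] = entry_id
        pos += s

    individuals = pd.DataFrame(
        {"id": ids, "sex": sex, "age_days": age, "tree_id": tree_col, "entry_id": entry_col}
    )
    nest_sites = pd.DataFrame(nest_rows, columns=["tree_id", "nest_id", "entry_id", "x", "y"])
    return individuals, nest_sites


# ---------------------------------------------------------------------------
# social observations
# ---------------------------------------------------------------------------

def _random_pair(rng, ids):
    i, j = rng.choice(len(ids), size=2, replace=False)
    return ids[i], ids[j]


def simulate_social_observations(individuals: pd.DataFrame, config: ObservationConfig, seed: int):
    """Simulate foraging sightings and typed dyadic interactions.

    Foraging groups assemble around a seed bird with a preference for its
    tree-mates (`tree_assortativity`); allopreening concentrates within
    shared nest entries; close tolerance within shared trees; aggression
    is unstructured. Returns ``(sightings, interactions)`` DataFrames.
    """
    rng = np.random.default_rng(seed)
    ids = list(individuals["id"])
    tree = dict(zip(individuals["id"], individuals["tree_id"]))
    entry_groups = {
        e: list(g["id"]) for e, g in individuals.dropna(subset=["entry_id"]).groupby("entry_id")
    }
    tree_groups = {
        t: list(g["id"]) for t, g in individuals.dropna(subset=["tree_id"]).groupby("tree_id")
    }
    multi_entries = [e for e, m in entry_groups.items() if len(m) >= 2]
    multi_trees = [t for t, m in tree_groups.items() if len(m) >= 2]

    if config.n_sessions == 0:
        warnings.warn("zero observation sessions requested; returning empty tables")
        return (
            pd.DataFrame(columns=["session", "group", "individual"]),
            pd.DataFrame(columns=["session", "kind", "id_i", "id_j"]),
        )

    sight_rows = []
    inter_rows = []
    idx = np.arange(len(ids))
    for s in range(1, config.n_sessions + 1):
        session = f"S{s:03d}"
        for g in range(1, config.groups_per_session + 1):
            size = min(len(ids), 1 + rng.poisson(config.mean_group_size - 1.0))
            seed_i = int(rng.integers(len(ids)))
            seed_tree = tree[ids[seed_i]]
            w = np.ones(len(ids))
            if not pd.isna(seed_tree):
                same = np.array(
                    [(not pd.isna(tree[i])) and tree[i] == seed_tree for i in ids], dtype=float
                )
                w += config.tree_assortativity * same
            w[seed_i] = 0.0
            w /= w.sum()
            others = rng.choice(idx, size=size - 1, replace=False, p=w) if size > 1 else []
            members = [ids[seed_i]] + [ids[k] for k in others]
            for m in sorted(members):
                sight_rows.append({"session": session, "group": f"{session}G{g}", "individual": m})

        def _emit(kind, rate, pool_groups, within_prob):
            for _ in range(rng.poisson(rate)):
                if pool_groups and rng.uniform() < within_prob:
                    grp = pool_groups[int(rng.integers(len(pool_groups)))]
                    members = entry_groups.get(grp) or tree_groups.get(grp)
                    a, b = _random_pair(rng, members)
                else:
                    a, b = _random_pair(rng, ids)
                inter_rows.append({"session": session, "kind": kind, "id_i": a, "id_j": b})

        _emit("allopreen", config.allopreen_rate, multi_entries, config.allopreen_within_entry_prob)
        _emit("tolerance", config.tolerance_rate, multi_trees, config.tolerance_within_tree_prob)
        _emit("aggression", config.aggression_rate, [], 0.0)
        _emit("mate", config.mate_obs_rate, multi_entries, 1.0)

    sightings = pd.DataFrame(sight_rows, columns=["session", "group", "individual"])
    interactions = pd.DataFrame(inter_rows, columns=["session", "kind", "id_i", "id_j"])
    return sightings, interactions


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def simulate_relatedness(
    individuals: pd.DataFrame,
    seed: int,
    kin_pairs: Optional[list] = None,
    background_mean: float = 0.02,
):
    """Pairwise relatedness matrix from a configured pedigree list.

    When `kin_pairs` (triples ``(id_a, id_b, expected_r)``) is omitted, a
    pedigree is derived from nest chambers: the first two occupants of a
    chamber are an unrelated breeding pair, further occupants are their
    offspring (r = 0.5 to each parent and to each other). Background
    (unrelated) values are small Beta noise with the given mean; kin values
    are the expectation plus estimation noise. Symmetric, diagonal NaN.
    """
    rng = np.random.default_rng(seed)
    ids = list(individuals["id"])
    n = len(ids)
    pos = {b: k for k, b in enumerate(ids)}

    if kin_pairs is None:
        kin_pairs = []
        for _, grp in individuals.dropna(subset=["entry_id"]).groupby("entry_id"):
            members = list(grp["id"])
            parents, offspring = members[:2], members[2:]
            for child in offspring:
                for par in parents:
                    kin_pairs.append((par, child, 0.5))
            for a, b in itertools.combinations(offspring, 2):
                kin_pairs.append((a, b, 0.5))

    b_mean = background_mean
    ab = 20.0
    mat = rng.beta(b_mean * ab, (1 - b_mean) * ab, size=(n, n))
    mat = np.triu(mat, 1)
    mat = mat + mat.T
    for a, b, r in kin_pairs:
        val = float(np.clip(rng.normal(r, 0.05), 0.0, 1.0))
        mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = val
    np.fill_diagonal(mat, np.nan)
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# call types, embeddings and traces
# ---------------------------------------------------------------------------

def simulate_repertoire_counts(alpha, beta, X, totals, theta, rng):
    """Draw call-type counts from the Dirichlet-multinomial chain.

    ``s_i = exp(log(alpha) + X_i @ beta)``, ``pi_i = s_i / sum(s_i)``,
    ``p_i ~ dirichlet(pi_i * theta)``, ``x_i ~ multinomial(N_i, p_i)``.

    Parameters
    ----------
    alpha : (K,) simplex of average type proportions.
    beta : (p, K) covariate effects on log-proportions.
    X : (n, p) covariate matrix.
    totals : (n,) calls per individual.
    """
    alpha = np.asarray(alpha, float)
    if (alpha < 0).any() or not np.isclose(alpha.sum(), 1.0):
        raise ConfigError("alpha must be a simplex")
    beta = np.atleast_2d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    log_s = np.log(alpha)[None, :] + X @ beta
    log_s -= log_s.max(axis=1, keepdims=True)
    s = np.exp(log_s)
    pi = s / s.sum(axis=1, keepdims=True)
    counts = np.empty_like(pi, dtype=int)
    for i in range(pi.shape[0]):
        p = rng.dirichlet(pi[i] * theta)
        counts[i] = rng.multinomial(int(totals[i]), p)
    return counts


def _trace_basis(trace_len, embed_dim):
    t = np.linspace(0.0, 1.0, trace_len)
    phases = np.array([0.3, 1.1, 2.0, 0.7, 1.7, 2.6])
    basis = np.stack(
        [np.sin((k + 1) * np.pi * t + phases[k % len(phases)]) for k in range(embed_dim)]
    )
    return t, basis


def simulate_calls(
    individuals: pd.DataFrame,
    config: CallConfig,
    seed: int,
    similarity_edges: Optional[list] = None,
    similarity_effect: float = 0.0,
):
    """Simulate classified calls with F0 traces and per-call embeddings.

    Call types follow the Dirichlet-multinomial generative model with
    per-type age and sex effects on log-proportions. Each call carries an
    F0 trace synthesised from a latent embedding: individual centroids
    (between-individual structure), within-individual scatter whose scale
    can depend on covariates (`gamma_within`), and an optional dyad-level
    push applied along `similarity_edges` — a positive `similarity_effect`
    moves connected individuals' centroids apart (less similar calls).

    Returns
    -------
    (calls, traces, truth)
        ``calls``: call_id, individual_id, recording_id, call_type,
        n_peaks_true. ``traces``: dict call_id -> F0 array (Hz).
        ``truth``: :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    ids = list(individuals["id"])
    n = len(ids)
    K = len(config.alpha)
    if K != len(CALL_TYPES):
        raise ConfigError(f"alpha must have {len(CALL_TYPES)} entries")

    age = individuals["age_days"].to_numpy(float)
    z_age = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    female = (individuals["sex"] == "F").astype(float).to_numpy()
    X = np.column_stack([z_age, female])
    B = np.vstack([config.beta_age, config.beta_sex])

    totals = np.maximum(
        config.min_calls_per_individual, rng.poisson(config.mean_calls, size=n)
    )
    counts = simulate_repertoire_counts(np.asarray(config.alpha), B, X, totals, config.theta, rng)

    # individual centroids, optionally pushed apart/together along edges
    centroids = rng.normal(0.0, config.sigma_between, size=(n, config.embed_dim))
    pos = {b: k for k, b in enumerate(ids)}
    if similarity_edges and similarity_effect != 0.0:
        for a, b in similarity_edges:
            ia, ib = pos[a], pos[b]
            mid = (centroids[ia] + centroids[ib]) / 2.0
            centroids[ia] = mid + (centroids[ia] - mid) * (1.0 + similarity_effect)
            centroids[ib] = mid + (centroids[ib] - mid) * (1.0 + similarity_effect)

    # within-individual spread scaled by covariate effects (log scale)
    log_spread = np.full(n, np.log(config.sigma_within))
    cov_map = {"age": z_age, "sex": female}
    for name, g in config.gamma_within.items():
        log_spread += g * cov_map[name]
    spread = np.exp(log_spread)

    # AM-peak means per individual
    cov_map_peaks = dict(cov_map)
    if "tree_size" in config.peak_slopes:
        ts = individuals.groupby("tree_id")["id"].transform("count").to_numpy(float)
        ts = np.where(np.isfinite(ts), ts, np.nanmean(ts))
        cov_map_peaks["tree_size"] = (ts - np.nanmean(ts)) / (np.nanstd(ts) or 1.0)
    log_peaks = np.full(n, np.log(config.mean_peaks) if config.mean_peaks > 0 else -np.inf)
    for name, g in config.peak_slopes.items():
        log_peaks += g * cov_map_peaks[name]

    t, basis = _trace_basis(config.trace_len, config.embed_dim)
    call_rows = []
    traces = {}
    for i, bird in enumerate(ids):
        order = rng.permuted(np.repeat(np.arange(K), counts[i]))
        n_calls = order.size
        for c in range(n_calls):
            rec = c // config.calls_per_recording + 1
            call_id = f"{bird}_c{c + 1:03d}"
            emb = centroids[i] + rng.normal(0.0, spread[i], size=config.embed_dim)
            f0 = config.f0_base_hz + config.f0_scale_hz * (emb @ basis)
            n_peaks = int(rng.poisson(np.exp(log_peaks[i]))) if np.isfinite(log_peaks[i]) else 0
            if n_peaks > 0 and config.bump_height_hz > 0:
                centers = rng.uniform(0.06, 0.94, size=n_peaks)
                widths = rng.uniform(0.008, 0.015, size=n_peaks)
                heights = config.bump_height_hz * rng.uniform(0.9, 1.4, size=n_peaks)
                for ck, wk, hk in zip(centers, widths, heights):
                    f0 = f0 + hk * np.exp(-0.5 * ((t - ck) / wk) ** 2)
            traces[call_id] = f0
            call_rows.append(
                {
                    "call_id": call_id,
                    "individual_id": bird,
                    "recording_id": f"{bird}_r{rec}",
                    "call_type": CALL_TYPES[order[c]],
                    "n_peaks_true": n_peaks,
                }
            )
    calls = pd.DataFrame(
        call_rows, columns=["call_id", "individual_id", "recording_id", "call_type", "n_peaks_true"]
    )
    truth = GroundTruth(
        seed=seed,
        sigma_between=config.sigma_between,
        sigma_within=config.sigma_within,
        gamma_within=config.gamma_within,
        alpha=config.alpha,
        beta_age=config.beta_age,
        beta_sex=config.beta_sex,
        theta=config.theta,
        similarity_effect=similarity_effect,
        mean_peaks=config.mean_peaks,
        peak_slopes=config.peak_slopes,
    )
    return calls, traces, truth


# ---------------------------------------------------------------------------
# direct model-level generators (for calibration / recovery tests)
# ---------------------------------------------------------------------------

def simulate_dyadic_distance_data(
    seed: int,
    n_dyads: int = 150,
    obs_per_dyad: int = 8,
    sigma_dyad: float = 0.4,
    sigma_rec: float = 0.1,
    sigma: float = 0.2,
    alpha_bar: float = 1.0,
    n_recordings: Optional[int] = None,
):
    """Draw between-individual distance observations from the dyadic model.

    Each observation pairs two distinct recordings from a shared pool, so
    recording offsets are informed by repeated appearances. Returns
    ``(observations, truth)`` where truth holds the drawn dyad and
    recording effects alongside the hyperparameters.
    """
    rng = np.random.default_rng(seed)
    n_recordings = n_recordings or max(20, n_dyads // 2)
    a_dyad = rng.normal(alpha_bar, sigma_dyad, size=n_dyads)
    a_rec = rng.normal(0.0, sigma_rec, size=n_recordings)
    rows = []
    for d in range(n_dyads):
        for _ in range(obs_per_dyad):
            r1, r2 = rng.choice(n_recordings, size=2, replace=False)
            y = a_dyad[d] + a_rec[r1] + a_rec[r2] + rng.normal(0.0, sigma)
            rows.append(
                {"distance": y, "dyad_id": f"D{d:04d}", "rec_i": f"R{r1:04d}", "rec_j": f"R{r2:04d}"}
            )
    obs = pd.DataFrame(rows)
    truth = {
        "alpha_bar": alpha_bar,
        "sigma": sigma,
        "sigma_dyad": sigma_dyad,
        "sigma_rec": sigma_rec,
        "alpha_dyad": pd.Series(a_dyad, index=[f"D{d:04d}" for d in range(n_dyads)]),
    }
    return obs, truth


def simulate_within_distance_data(
    seed: int,
    n_individuals: int = 60,
    calls_per_individual: int = 15,
    calls_per_recording: int = 5,
    sigma_ind: float = 0.05,
    sigma_rec_pair: float = 0.05,
    sigma_call: float = 0.1,
    sigma: float = 0.2,
    alpha_bar: float = 1.0,
    alpha_same_rec: float = -0.05,
):
    """Draw within-individual distance observations from the diversity model.

    Calls are grouped into recordings of `calls_per_recording`; all
    within-individual call pairs are observed. Returns ``(observations,
    truth)``.
    """
    rng = np.random.default_rng(seed)
    a_ind = rng.normal(alpha_bar, sigma_ind, size=n_individuals)
    rows = []
    rp_effects: dict = {}
    a_ind_index = []
    for i in range(n_individuals):
        bird = f"B{i:03d}"
        a_ind_index.append(bird)
        calls = [f"{bird}_c{c:03d}" for c in range(calls_per_individual)]
        recs = {c: f"{bird}_r{k // calls_per_recording}" for k, c in enumerate(calls)}
        a_call = {c: rng.normal(0.0, sigma_call) for c in calls}
        for ci, cj in itertools.combinations(calls, 2):
            ri, rj = recs[ci], recs[cj]
            rp = tuple(sorted((ri, rj)))
            if rp not in rp_effects:
                rp_effects[rp] = rng.normal(0.0, sigma_rec_pair)
            same = ri == rj
            y = (
                a_ind[i]
                + (alpha_same_rec if same else 0.0)
                + rp_effects[rp]
                + a_call[ci]
                + a_call[cj]
                + rng.normal(0.0, sigma)
            )
            rows.append(
                {
                    "distance": y,
                    "individual_id": bird,
                    "call_i": ci,
                    "call_j": cj,
                    "rec_i": ri,
                    "rec_j": rj,
                    "same_recording": same,
                }
            )
    obs = pd.DataFrame(rows)
    truth = {
        "alpha_bar": alpha_bar,
        "sigma": sigma,
        "sigma_ind": sigma_ind,
        "sigma_rec_pair": sigma_rec_pair,
        "sigma_call": sigma_call,
        "alpha_same_rec": alpha_same_rec,
        "alpha_ind": pd.Series(a_ind, index=a_ind_index),
    }
    return obs, truth


def simulate_measured_outcomes(
    seed: int,
    n: int = 80,
    slopes: dict | None = None,
    intercept: float = 0.0,
    sigma_resid: float = 0.3,
    est_sd_scale: float = 0.1,
):
    """Individual-level measured outcomes with known regression structure.

    Latent truth ``z = a + X @ slopes + noise``; the observed estimate is
    ``z`` corrupted by per-unit measurement noise with reported sd
    (heterogeneous, mean `est_sd_scale`). Returns ``(outcomes, predictors,
    truth)``.
    """
    rng = np.random.default_rng(seed)
    slopes = dict(slopes or {"age": 0.5})
    X = pd.DataFrame({k: rng.normal(size=n) for k in slopes}, index=[f"B{i:03d}" for i in range(n)])
    latent = intercept + X.to_numpy() @ np.array(list(slopes.values())) + rng.normal(0, sigma_resid, n)
    est_sd = est_sd_scale * rng.uniform(0.5, 1.5, size=n)
    est_mean = latent + rng.normal(0.0, est_sd)
    outcomes = pd.DataFrame(
        {"unit_id": X.index, "est_mean": est_mean, "est_sd": est_sd}
    )
    truth = {"intercept": intercept, "slopes": slopes, "sigma_resid": sigma_resid}
    return outcomes, X.reset_index(names="unit_id"), truth


def simulate_dyadic_measured_outcomes(
    seed: int,
    n_dyads: int = 300,
    n_individuals: int = 60,
    slopes: dict | None = None,
    intercept: float = 0.0,
    sigma_ind: float = 0.2,
    sigma_resid: float = 0.3,
    est_sd_scale: float = 0.1,
    binary_predictors: tuple = ("tolerance", "mate"),
):
    """Dyad-level measured outcomes with multi-membership structure.

    Each dyad outcome is ``a + X @ slopes + u_i + u_j + noise`` with
    individual random effects u; binary predictors are Bernoulli(0.3)
    edges, others standard normal. Returns ``(outcomes, predictors,
    truth)`` where predictors carry ``id_i``/``id_j``.
    """
    rng = np.random.default_rng(seed)
    slopes = dict(slopes or {"tolerance": 0.3, "relatedness": 0.0})
    birds = [f"B{i:03d}" for i in range(n_individuals)]
    u = rng.normal(0.0, sigma_ind, size=n_individuals)
    pairs = list(itertools.combinations(range(n_individuals), 2))
    take = rng.choice(len(pairs), size=min(n_dyads, len(pairs)), replace=False)
    rows = []
    for k in sorted(take):
        i, j = pairs[k]
        x = {}
        for name in slopes:
            if name in binary_predictors:
                x[name] = float(rng.uniform() < 0.3)
            else:
                x[name] = rng.normal()
        latent = intercept + sum(slopes[m] * x[m] for m in slopes) + u[i] + u[j]
        latent += rng.normal(0.0, sigma_resid)
        sd = est_sd_scale * rng.uniform(0.5, 1.5)
        rows.append(
            {
                "dyad_id": f"{birds[i]}|{birds[j]}",
                "id_i": birds[i],
                "id_j": birds[j],
                "est_mean": latent + rng.normal(0.0, sd),
                "est_sd": sd,
                **x,
            }
        )
    df = pd.DataFrame(rows)
    outcomes = df[["dyad_id", "id_i", "id_j", "est_mean", "est_sd"]]
    predictors = df[["dyad_id", "id_i", "id_j", *slopes]]
    truth = {"intercept": intercept, "slopes": slopes, "sigma_ind": sigma_ind, "sigma_resid": sigma_resid}
    return outcomes, predictors, truth


# ---------------------------------------------------------------------------
# table output
# ---------------------------------------------------------------------------

def write_tables(
    outdir,
    individuals=None,
    nest_sites=None,
    sightings=None,
    interactions=None,
    relatedness=None,
    calls=None,
    traces=None,
    truth: GroundTruth | None = None,
    trace_step_s: float = 0.0025,
):
    """Write the generated inputs as delimited text under `outdir`.

    Individuals, nests, sightings, interactions and calls are TSV;
    relatedness a square TSV matrix; F0 traces one TSV per recording with
    columns call_id, time_s, f0_hz; ground truth JSON.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    named = {
        "individuals.tsv": individuals,
        "nest_sites.tsv": nest_sites,
        "sightings.tsv": sightings,
        "interactions.tsv": interactions,
        "calls.tsv": calls,
    }
    for fname, df in named.items():
        if df is not None:
            df.to_csv(out / fname, sep="\t", index=False)
    if relatedness is not None:
        relatedness.to_csv(out / "relatedness.tsv", sep="\t")
    if traces is not None and calls is not None:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for rec, grp in calls.groupby("recording_id"):
            rows = []
            for cid in grp["call_id"]:
                f0 = traces[cid]
                for k, v in enumerate(f0):
                    rows.append((cid, k * trace_step_s, v))
            pd.DataFrame(rows, columns=["call_id", "time_s", "f0_hz"]).to_csv(
                tdir / f"{rec}.tsv", sep="\t", index=False
            )
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    return out
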