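"""Hierarchical Bayesian decomposition of acoustic distances.

Two models, both with a normal likelihood on (internally standardised)
DTW distances and the printed weakly-informative priors:

Between-individual (dyadic similarity) model
    ``distance ~ normal(mu, sigma)`` with
    ``mu = alpha_dyad + alpha_rec[i] + alpha_rec[j]``,
    ``alpha_dyad ~ normal(alpha_bar, sigma_dyad)``,
    ``alpha_bar ~ normal(0, 0.5)``, ``alpha_rec ~ normal(0, sigma_rec)``
    and ``sigma, sigma_dyad, sigma_rec ~ exponential(2)``. The per-dyad
    level ``alpha_dyad`` is the similarity measure (a larger value = less
    similar calls); recording offsets soak up repeated comparisons of the
    same recordings, entering once per recording and additively for the
    two recordings of a pair.

Within-individual (diversity) model
    ``mu = alpha_ind + alpha_same_rec + alpha_rec_pair + alpha_call_i +
    alpha_call_j`` with ``alpha_ind ~ normal(alpha_bar, sigma_ind)``,
    ``alpha_bar ~ normal(0, 0.25)``, ``alpha_rec_pair ~ normal(0,
    sigma_rec_pair)``, ``alpha_call ~ normal(0, sigma_call)``,
    ``sigma ~ exponential(5)`` and ``sigma_ind, sigma_rec_pair,
    sigma_call ~ exponential(3)``. ``alpha_ind`` is the per-individual
    contact-call diversity; ``alpha_same_rec`` is a scalar offset for
    pairs drawn from a single recording (prior normal(0, 0.5)).

Sampling is blocked Gibbs: every location parameter has a conjugate
normal conditional (recording offsets are drawn jointly from their
multivariate normal conditional; call offsets are updated in graph-coloured
blocks), and the scale hyperparameters are updated by univariate slice
sampling under their exponential priors. Posterior means and standard
deviations per dyad / individual are exported for stage-2 models, with the
standardisation inverted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from vocsocial.models.base import MCMCResults, SamplerConfig, slice_sample

__all__ = [
    "DyadicDistanceModel",
    "WithinIndividualDistanceModel",
    "DyadicDistanceResults",
    "WithinDistanceResults",
    "export_summaries",
]


def _check_distances(y, frame):
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        rows = frame.index[bad[:10]].tolist()
        raise ValueError(f"non-finite distances at rows {rows}" + (" ..." if bad.size > 10 else ""))


def _standardize(y):
    shift = float(y.mean())
    sd = float(y.std())
    scale = sd if sd > 0 else 1.0
    return (y - shift) / scale, shift, scale


def _sample_scale(ss, n, rate, current, rng):
    """Slice-sample a scale parameter (on log scale).

    Target: n deviates with sum of squares `ss` ~ normal(0, s), prior
    s ~ exponential(rate); includes the log-Jacobian of s = exp(t).
    """

    def logp(t):
        if t > 12.0 or t < -14.0:
            return -np.inf
        s = np.exp(t)
        return -n * t - ss / (2.0 * s * s) - rate * s + t

    return float(np.exp(slice_sample(logp, np.log(current), rng, w=1.0)))


def _chain_rng(seed, chain):
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(chain)]))


class DyadicDistanceResults(MCMCResults):
    """Posterior for the between-individual similarity model."""

    def __init__(self, draws, dyad_ids, rec_ids, shift, scale, **kw):
        super().__init__(draws, **kw)
        self.dyad_ids = list(dyad_ids)
        self.rec_ids = list(rec_ids)
        self.shift_ = shift
        self.scale_ = scale

    def dyad_estimates(self, scale: str = "original") -> pd.DataFrame:
        """Per-dyad similarity level: mean, sd, 89% PI, Rhat."""
        if scale == "original":
            return self.posterior_table("alpha_dyad", self.dyad_ids, scale=self.scale_, shift=self.shift_)
        return self.posterior_table("alpha_dyad", self.dyad_ids)

    unit_estimates = dyad_estimates

    def hyper_estimates(self, scale: str = "original") -> pd.DataFrame:
        """Hyperparameters, optionally mapped back to the raw distance scale."""
        tab = self.summary(["alpha_bar", "sigma", "sigma_dyad", "sigma_rec"])
        if scale == "original":
            s = self.scale_
            adj = tab["parameter"].map({"alpha_bar": (s, self.shift_)}).fillna("")
            for i, row in tab.iterrows():
                mul, add = (s, self.shift_) if row["parameter"] == "alpha_bar" else (s, 0.0)
                for col in ("mean", "pi89_low", "pi89_high"):
                    tab.loc[i, col] = row[col] * mul + add
                tab.loc[i, "sd"] = row["sd"] * mul
        return tab

    def fit_report(self) -> dict:
        worst = max(float(np.max(self.rhat(n))) for n in self.hyperparameters)
        return {
            "model": "dyadic_distance",
            "n_dyads": len(self.dyad_ids),
            "n_recordings": len(self.rec_ids),
            "worst_hyper_rhat": worst,
            "seed": self.config.seed if self.config else None,
            "standardization": {"shift": self.shift_, "scale": self.scale_},
        }


class DyadicDistanceModel:
    """Between-individual acoustic-distance model (see module docstring).

    Parameters
    ----------
    observations : DataFrame
        Columns ``distance``, ``dyad_id``, ``rec_i``, ``rec_j`` — e.g. the
        output of :func:`vocsocial.acoustics.between_individual_distances`.
    standardize : bool
        Z-score distances before fitting so the printed priors are weakly
        informative on the model scale (inverted on export).
    """

    PRIORS = {
        "alpha_bar": (0.0, 0.5),
        "sigma_rate": 2.0,
        "sigma_dyad_rate": 2.0,
        "sigma_rec_rate": 2.0,
    }

    def __init__(self, observations: pd.DataFrame, standardize: bool = True):
        obs = observations.reset_index(drop=True)
        y = obs["distance"].to_numpy(float)
        _check_distances(y, obs)
        self.dyad_ids, self.dyad_idx = np.unique(obs["dyad_id"], return_inverse=True)
        if len(self.dyad_ids) < 2:
            raise ValueError("need at least 2 dyads")
        recs = pd.concat([obs["rec_i"], obs["rec_j"]])
        self.rec_ids = np.unique(recs)
        rec_pos = {r: k for k, r in enumerate(self.rec_ids)}
        self.r1 = obs["rec_i"].map(rec_pos).to_numpy()
        self.r2 = obs["rec_j"].map(rec_pos).to_numpy()
        if standardize:
            self.y, self.shift_, self.scale_ = _standardize(y)
        else:
            self.y, self.shift_, self.scale_ = y, 0.0, 1.0
        self.n_obs = len(self.y)
        self.n_dyads = len(self.dyad_ids)
        self.n_recs = len(self.rec_ids)
        # constant Gram matrix of the recording incidence (two unit entries
        # per observation; a repeated recording gets coefficient 2)
        G = np.zeros((self.n_recs, self.n_recs))
        np.add.at(G, (self.r1, self.r1), 1.0)
        np.add.at(G, (self.r2, self.r2), 1.0)
        np.add.at(G, (self.r1, self.r2), 1.0)
        np.add.at(G, (self.r2, self.r1), 1.0)
        self._gram = G
        self._n_per_dyad = np.bincount(self.dyad_idx, minlength=self.n_dyads)

    @staticmethod
    def sample_priors(n: int, seed: int = 0) -> pd.DataFrame:
        """Monte-Carlo draws from the printed priors (prior-predictive aid)."""
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "alpha_bar": rng.normal(0.0, 0.5, n),
                "sigma": rng.exponential(1 / 2.0, n),
                "sigma_dyad": rng.exponential(1 / 2.0, n),
                "sigma_rec": rng.exponential(1 / 2.0, n),
            }
        )

    def _rec_sums(self, resid):
        b = np.bincount(self.r1, weights=resid, minlength=self.n_recs)
        b += np.bincount(self.r2, weights=resid, minlength=self.n_recs)
        return b

    def fit(self, config: SamplerConfig = SamplerConfig()) -> DyadicDistanceResults:
        y, d_idx, r1, r2 = self.y, self.dyad_idx, self.r1, self.r2
        n_d, n_r = self.n_dyads, self.n_recs
        mu0, tau0 = self.PRIORS["alpha_bar"]
        keep = config.draws
        store = {
            "alpha_bar": np.empty((config.chains, keep)),
            "sigma": np.empty((config.chains, keep)),
            "sigma_dyad": np.empty((config.chains, keep)),
            "sigma_rec": np.empty((config.chains, keep)),
            "alpha_dyad": np.empty((config.chains, keep, n_d)),
            "alpha_rec": np.empty((config.chains, keep, n_r)),
        }
        dyad_mean = np.bincount(d_idx, weights=y, minlength=n_d) / np.maximum(self._n_per_dyad, 1)

        for chain in range(config.chains):
            rng = _chain_rng(config.seed, chain)
            sigma = max(rng.exponential(0.5), 0.05)
            sigma_d = max(rng.exponential(0.5), 0.05)
            sigma_r = max(rng.exponential(0.5), 0.05)
            a_bar = float(y.mean() + rng.normal(0, 0.2))
            a_dyad = dyad_mean + rng.normal(0, 0.1, n_d)
            a_rec = np.zeros(n_r)
            eye = np.eye(n_r)

            for it in range(config.warmup + keep):
                # dyad levels (conjugate, independent given recordings)
                resid = y - a_rec[r1] - a_rec[r2]
                s_d = np.bincount(d_idx, weights=resid, minlength=n_d)
                prec = self._n_per_dyad / sigma**2 + 1.0 / sigma_d**2
                mean = (s_d / sigma**2 + a_bar / sigma_d**2) / prec
                a_dyad = mean + rng.standard_normal(n_d) / np.sqrt(prec)

                # hyper-mean
                prec0 = 1.0 / tau0**2 + n_d / sigma_d**2
                mean0 = (mu0 / tau0**2 + a_dyad.sum() / sigma_d**2) / prec0
                a_bar = mean0 + rng.standard_normal() / np.sqrt(prec0)

                # recording offsets: joint multivariate-normal conditional
                resid = y - a_dyad[d_idx]
                b = self._rec_sums(resid) / sigma**2
                lam = self._gram / sigma**2 + eye / sigma_r**2
                L = cholesky(lam, lower=True)
                mu_rec = cho_solve((L, True), b)
                a_rec = mu_rec + solve_triangular(L.T, rng.standard_normal(n_r), lower=False)

                # scales (slice sampling, exponential priors)
                resid = y - a_dyad[d_idx] - a_rec[r1] - a_rec[r2]
                sigma = _sample_scale((resid**2).sum(), self.n_obs, self.PRIORS["sigma_rate"], sigma, rng)
                sigma_d = _sample_scale(
                    ((a_dyad - a_bar) ** 2).sum(), n_d, self.PRIORS["sigma_dyad_rate"], sigma_d, rng
                )
                sigma_r = _sample_scale((a_rec**2).sum(), n_r, self.PRIORS["sigma_rec_rate"], sigma_r, rng)

                # interweaving: refresh the hyper-mean in the non-centred
                # parameterisation (deviations held fixed) to break the
                # alpha_bar <-> alpha_dyad random-walk coupling
                u_dev = (a_dyad - a_bar) / sigma_d
                r_trans = resid + a_bar  # y - recordings - sigma_d * u
                prec_t = self.n_obs / sigma**2 + 1.0 / tau0**2
                mean_t = (r_trans.sum() / sigma**2 + mu0 / tau0**2) / prec_t
                a_bar = mean_t + rng.standard_normal() / np.sqrt(prec_t)
                a_dyad = a_bar + sigma_d * u_dev

                if it >= config.warmup:
                    k = it - config.warmup
                    store["alpha_bar"][chain, k] = a_bar
                    store["sigma"][chain, k] = sigma
                    store["sigma_dyad"][chain, k] = sigma_d
                    store["sigma_rec"][chain, k] = sigma_r
                    store["alpha_dyad"][chain, k] = a_dyad
                    store["alpha_rec"][chain, k] = a_rec

        res = DyadicDistanceResults(
            store,
            dyad_ids=self.dyad_ids,
            rec_ids=self.rec_ids,
            shift=self.shift_,
            scale=self.scale_,
            hyperparameters=("alpha_bar", "sigma", "sigma_dyad", "sigma_rec"),
            config=config,
            info={"n_obs": self.n_obs},
        )
        res.check_convergence()
        return res


class WithinDistanceResults(MCMCResults):
    """Posterior for the within-individual diversity model."""

    def __init__(self, draws, individual_ids, shift, scale, **kw):
        super().__init__(draws, **kw)
        self.individual_ids = list(individual_ids)
        self.shift_ = shift
        self.scale_ = scale

    def individual_estimates(self, scale: str = "original") -> pd.DataFrame:
        """Per-individual diversity (alpha_ind): mean, sd, 89% PI, Rhat."""
        if scale == "original":
            return self.posterior_table("alpha_ind", self.individual_ids, scale=self.scale_, shift=self.shift_)
        return self.posterior_table("alpha_ind", self.individual_ids)

    unit_estimates = individual_estimates

    def hyper_estimates(self, scale: str = "original") -> pd.DataFrame:
        tab = self.summary(
            ["alpha_bar", "alpha_same_rec", "sigma", "sigma_ind", "sigma_rec_pair", "sigma_call"]
        )
        if scale == "original":
            for i, row in tab.iterrows():
                mul = self.scale_
                add = self.shift_ if row["parameter"] == "alpha_bar" else 0.0
                for col in ("mean", "pi89_low", "pi89_high"):
                    tab.loc[i, col] = row[col] * mul + add
                tab.loc[i, "sd"] = row["sd"] * mul
        return tab

    def fit_report(self) -> dict:
        worst = max(float(np.max(self.rhat(n))) for n in self.hyperparameters)
        return {
            "model": "within_distance",
            "n_individuals": len(self.individual_ids),
            "worst_hyper_rhat": worst,
            "seed": self.config.seed if self.config else None,
            "standardization": {"shift": self.shift_, "scale": self.scale_},
        }


class WithinIndividualDistanceModel:
    """Within-individual acoustic-distance (diversity) model.

    Parameters
    ----------
    observations : DataFrame
        Columns ``distance``, ``individual_id``, ``call_i``, ``call_j``,
        ``rec_i``, ``rec_j``, ``same_recording`` — e.g. the output of
        :func:`vocsocial.acoustics.within_individual_distances`.
    """

    PRIORS = {
        "alpha_bar": (0.0, 0.25),
        "alpha_same_rec": (0.0, 0.5),
        "sigma_rate": 5.0,
        "sigma_ind_rate": 3.0,
        "sigma_rec_pair_rate": 3.0,
        "sigma_call_rate": 3.0,
    }

    def __init__(self, observations: pd.DataFrame, standardize: bool = True):
        obs = observations.reset_index(drop=True)
        y = obs["distance"].to_numpy(float)
        _check_distances(y, obs)
        self.individual_ids, self.ind_idx = np.unique(obs["individual_id"], return_inverse=True)
        if len(self.individual_ids) < 2:
            raise ValueError("need at least 2 individuals with repeated calls")
        rp = [tuple(sorted(p)) for p in zip(obs["rec_i"], obs["rec_j"])]
        self.rp_ids, self.rp_idx = np.unique(np.array([f"{a}~{b}" for a, b in rp]), return_inverse=True)
        calls = pd.concat([obs["call_i"], obs["call_j"]])
        self.call_ids = np.unique(calls)
        call_pos = {c: k for k, c in enumerate(self.call_ids)}
        self.c1 = obs["call_i"].map(call_pos).to_numpy()
        self.c2 = obs["call_j"].map(call_pos).to_numpy()
        if np.any(self.c1 == self.c2):
            raise ValueError("a call paired with itself")
        self.same = obs["same_recording"].to_numpy(bool)
        if standardize:
            self.y, self.shift_, self.scale_ = _standardize(y)
        else:
            self.y, self.shift_, self.scale_ = y, 0.0, 1.0
        self.n_obs = len(self.y)
        self.n_ind = len(self.individual_ids)
        self.n_rp = len(self.rp_ids)
        self.n_call = len(self.call_ids)
        self._n_per_ind = np.bincount(self.ind_idx, minlength=self.n_ind)
        self._n_per_rp = np.bincount(self.rp_idx, minlength=self.n_rp)
        self._n_per_call = np.bincount(self.c1, minlength=self.n_call) + np.bincount(
            self.c2, minlength=self.n_call
        )
        # colour the call co-occurrence graph so same-colour calls never
        # share an observation and can be updated in one vectorised block
        g = nx.Graph()
        g.add_nodes_from(range(self.n_call))
        g.add_edges_from(zip(self.c1.tolist(), self.c2.tolist()))
        colouring = nx.greedy_color(g, strategy="largest_first")
        colours = np.array([colouring[k] for k in range(self.n_call)])
        self._colour_blocks = []
        for colour in range(colours.max() + 1):
            members = np.flatnonzero(colours == colour)
            side1 = np.flatnonzero(np.isin(self.c1, members))
            side2 = np.flatnonzero(np.isin(self.c2, members))
            self._colour_blocks.append((members, side1, side2))

    @staticmethod
    def sample_priors(n: int, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "alpha_bar": rng.normal(0.0, 0.25, n),
                "alpha_same_rec": rng.normal(0.0, 0.5, n),
                "sigma": rng.exponential(1 / 5.0, n),
                "sigma_ind": rng.exponential(1 / 3.0, n),
                "sigma_rec_pair": rng.exponential(1 / 3.0, n),
                "sigma_call": rng.exponential(1 / 3.0, n),
            }
        )

    def fit(self, config: SamplerConfig = SamplerConfig()) -> WithinDistanceResults:
        y = self.y
        ind, rp, c1, c2, same = self.ind_idx, self.rp_idx, self.c1, self.c2, self.same
        n_i, n_p, n_c = self.n_ind, self.n_rp, self.n_call
        keep = config.draws
        mu0, tau0 = self.PRIORS["alpha_bar"]
        mus, taus = self.PRIORS["alpha_same_rec"]
        n_same = int(same.sum())
        store = {
            "alpha_bar": np.empty((config.chains, keep)),
            "alpha_same_rec": np.empty((config.chains, keep)),
            "sigma": np.empty((config.chains, keep)),
            "sigma_ind": np.empty((config.chains, keep)),
            "sigma_rec_pair": np.empty((config.chains, keep)),
            "sigma_call": np.empty((config.chains, keep)),
            "alpha_ind": np.empty((config.chains, keep, n_i)),
        }
        ind_mean = np.bincount(ind, weights=y, minlength=n_i) / np.maximum(self._n_per_ind, 1)

        for chain in range(config.chains):
            rng = _chain_rng(config.seed, chain)
            sigma = max(rng.exponential(0.2), 0.02)
            sigma_i = max(rng.exponential(1 / 3.0), 0.02)
            sigma_p = max(rng.exponential(1 / 3.0), 0.02)
            sigma_c = max(rng.exponential(1 / 3.0), 0.02)
            a_bar = float(y.mean() + rng.normal(0, 0.1))
            a_ind = ind_mean + rng.normal(0, 0.05, n_i)
            a_same = 0.0
            a_rp = np.zeros(n_p)
            a_call = np.zeros(n_c)

            for it in range(config.warmup + keep):
                call_part = a_call[c1] + a_call[c2]

                # individual diversity levels
                resid = y - a_same * same - a_rp[rp] - call_part
                s_i = np.bincount(ind, weights=resid, minlength=n_i)
                prec = self._n_per_ind / sigma**2 + 1.0 / sigma_i**2
                mean = (s_i / sigma**2 + a_bar / sigma_i**2) / prec
                a_ind = mean + rng.standard_normal(n_i) / np.sqrt(prec)

                # hyper-mean
                prec0 = 1.0 / tau0**2 + n_i / sigma_i**2
                mean0 = (mu0 / tau0**2 + a_ind.sum() / sigma_i**2) / prec0
                a_bar = mean0 + rng.standard_normal() / np.sqrt(prec0)

                # same-recording scalar offset
                if n_same:
                    resid = y - a_ind[ind] - a_rp[rp] - call_part
                    s = resid[same].sum()
                    prec_s = n_same / sigma**2 + 1.0 / taus**2
                    a_same = (s / sigma**2 + mus / taus**2) / prec_s + rng.standard_normal() / np.sqrt(prec_s)

                # recording-pair offsets (one per observation group)
                resid = y - a_ind[ind] - a_same * same - call_part
                s_p = np.bincount(rp, weights=resid, minlength=n_p)
                prec_p = self._n_per_rp / sigma**2 + 1.0 / sigma_p**2
                a_rp = s_p / sigma**2 / prec_p + rng.standard_normal(n_p) / np.sqrt(prec_p)

                # call offsets, colour block by colour block
                base = y - a_ind[ind] - a_same * same - a_rp[rp]
                prec_c = self._n_per_call / sigma**2 + 1.0 / sigma_c**2
                for members, side1, side2 in self._colour_blocks:
                    s_c = np.zeros(n_c)
                    s_c += np.bincount(
                        c1[side1], weights=base[side1] - a_call[c2[side1]], minlength=n_c
                    )
                    s_c += np.bincount(
                        c2[side2], weights=base[side2] - a_call[c1[side2]], minlength=n_c
                    )
                    mean_c = s_c[members] / sigma**2 / prec_c[members]
                    a_call[members] = mean_c + rng.standard_normal(members.size) / np.sqrt(
                        prec_c[members]
                    )

                # scales
                resid = base - a_call[c1] - a_call[c2]
                sigma = _sample_scale((resid**2).sum(), self.n_obs, self.PRIORS["sigma_rate"], sigma, rng)
                sigma_i = _sample_scale(
                    ((a_ind - a_bar) ** 2).sum(), n_i, self.PRIORS["sigma_ind_rate"], sigma_i, rng
                )
                # interweaving (non-centred) update: resample sigma_ind with
                # the standardised deviations held fixed, then rescale; this
                # decorrelates the small variance component from its levels
                if sigma_i > 0:
                    u_dev = (a_ind - a_bar) / sigma_i
                    r_k = resid + (a_ind[ind] - a_bar)  # obs residual w/o the dev term
                    u_obs = u_dev[ind]
                    A = (u_obs**2).sum() / sigma**2
                    Bq = (r_k * u_obs).sum() / sigma**2
                    rate_i = self.PRIORS["sigma_ind_rate"]

                    def logp_nc(t):
                        if t > 6.0 or t < -14.0:
                            return -np.inf
                        s = np.exp(t)
                        return -0.5 * A * s * s + Bq * s - rate_i * s + t

                    sigma_i = float(np.exp(slice_sample(logp_nc, np.log(sigma_i), rng, w=1.0)))
                    a_ind = a_bar + sigma_i * u_dev

                    # translation interweaving for the hyper-mean
                    r_trans = r_k - sigma_i * u_obs  # y - controls - sigma_ind * u
                    prec_t = self.n_obs / sigma**2 + 1.0 / tau0**2
                    mean_t = ((r_trans + a_bar).sum() / sigma**2 + mu0 / tau0**2) / prec_t
                    a_bar = mean_t + rng.standard_normal() / np.sqrt(prec_t)
                    a_ind = a_bar + sigma_i * u_dev
                sigma_p = _sample_scale((a_rp**2).sum(), n_p, self.PRIORS["sigma_rec_pair_rate"], sigma_p, rng)
                sigma_c = _sample_scale((a_call**2).sum(), n_c, self.PRIORS["sigma_call_rate"], sigma_c, rng)

                if it >= config.warmup:
                    k = it - config.warmup
                    store["alpha_bar"][chain, k] = a_bar
                    store["alpha_same_rec"][chain, k] = a_same
                    store["sigma"][chain, k] = sigma
                    store["sigma_ind"][chain, k] = sigma_i
                    store["sigma_rec_pair"][chain, k] = sigma_p
                    store["sigma_call"][chain, k] = sigma_c
                    store["alpha_ind"][chain, k] = a_ind

        res = WithinDistanceResults(
            store,
            individual_ids=self.individual_ids,
            shift=self.shift_,
            scale=self.scale_,
            hyperparameters=("alpha_bar", "sigma", "sigma_ind", "sigma_rec_pair", "sigma_call"),
            config=config,
            info={"n_obs": self.n_obs, "n_calls": self.n_call, "n_rec_pairs": self.n_rp},
        )
        res.check_convergence()
        return res


def export_summaries(results) -> pd.DataFrame:
    """Machine-readable posterior summary per dyad or individual.

    One row per unit with posterior mean, sd, 89% equal-tailed interval and
    Rhat, on the original distance scale — the measurement-error inputs for
    stage-2 models.
    """
    return results.unit_estimates()
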