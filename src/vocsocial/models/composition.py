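"""Dirichlet-multinomial model of repertoire composition.

Call-type counts per individual follow

``x_i ~ multinomial(p_i)``; ``p_i ~ dirichlet(pi_i * theta)``;
``pi_i = s_i / sum(s_i)``; ``s_i = exp(log(alpha) + beta' A_i)``

with priors ``theta ~ exponential(0.2)``,
``alpha ~ dirichlet(5, 0.5, ..., 0.5)`` (the first, contact-call, type
dominates) and ``beta ~ normal(0, 0.5)`` per (covariate, type).
``theta`` controls how variable individuals are around their predicted
proportions ``pi_i`` (large theta = individuals concentrate at pi_i);
``beta`` moves each type's log-proportion with the covariates (sex enters
as a 0/1 column, giving per-type sex effects).

The per-individual probabilities ``p_i`` are integrated out analytically
(the compound is the Dirichlet-multinomial distribution), leaving a
low-dimensional posterior over (alpha, beta, theta) that is sampled with
an affine-invariant ensemble sampler (emcee). alpha lives on the simplex
via an additive log-ratio transform whose Jacobian combines with the
Dirichlet prior to the simple density ``prod_k alpha_k^{c_k}``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import emcee
from scipy.special import gammaln, logsumexp

from vocsocial.models.base import MCMCResults, SamplerConfig
from vocsocial.models.measurement import _prepare_design

__all__ = ["DirichletMultinomialModel", "DirichletMultinomialResults", "sex_contrast"]

DEFAULT_ALPHA_PRIOR = (5.0,)  # first type; remaining types get 0.5 each


class DirichletMultinomialResults(MCMCResults):
    """Posterior over (alpha, beta, theta) with contrast utilities."""

    def __init__(self, draws, type_names, covariate_names, X, x_means, x_sds, **kw):
        super().__init__(draws, **kw)
        self.type_names = list(type_names)
        self.covariate_names = list(covariate_names)
        self._X = X
        self._x_means = x_means
        self._x_sds = x_sds

    def alpha_estimates(self) -> pd.DataFrame:
        tab = self.posterior_table("alpha", self.type_names)
        return tab.rename(columns={"unit_id": "call_type"})

    def beta_estimates(self) -> pd.DataFrame:
        """Per (covariate, type) effect on log-proportions."""
        if not self.covariate_names:
            return pd.DataFrame()
        K = len(self.type_names)
        labels = [f"{c}:{t}" for c in self.covariate_names for t in self.type_names]
        tab = self.posterior_table("beta", labels)
        tab = tab.rename(columns={"unit_id": "effect"})
        tab["covariate"] = [lbl.split(":")[0] for lbl in tab["effect"]]
        tab["call_type"] = [lbl.split(":")[1] for lbl in tab["effect"]]
        return tab[["covariate", "call_type", "mean", "sd", "pi89_low", "pi89_high", "rhat"]]

    def _pi_draws(self, x_row):
        """Fitted proportions pi for one covariate row, per posterior draw."""
        log_alpha = np.log(self.stacked("alpha"))
        K = len(self.type_names)
        if self.covariate_names:
            B = self.stacked("beta").reshape(-1, len(self.covariate_names), K)
            eta = log_alpha + np.einsum("j,djk->dk", x_row, B)
        else:
            eta = log_alpha
        eta = eta - logsumexp(eta, axis=1, keepdims=True)
        return np.exp(eta)

    def fitted_pi(self) -> pd.DataFrame:
        """Posterior-mean predicted proportions per individual."""
        rows = [self._pi_draws(x).mean(axis=0) for x in self._X]
        return pd.DataFrame(rows, columns=self.type_names, index=self.info.get("individual_ids"))

    def sex_contrast(self, column: str = "sex") -> pd.DataFrame:
        """Female-minus-male contrast of fitted proportions per call type.

        Other covariates are held at their (standardised) mean of 0. The
        contrasts sum to ~0 across types by the simplex constraint.
        """
        if column not in self.covariate_names:
            raise ValueError(f"{column!r} was not a model covariate")
        j = self.covariate_names.index(column)
        col = self._X[:, j]
        if np.unique(col).size < 2:
            raise ValueError(f"covariate {column!r} is constant; contrast undefined")
        x_f = np.zeros(len(self.covariate_names))
        x_m = np.zeros(len(self.covariate_names))
        x_f[j] = 1.0
        diff = self._pi_draws(x_f) - self._pi_draws(x_m)
        lo, hi = np.quantile(diff, [0.055, 0.945], axis=0)
        return pd.DataFrame(
            {
                "call_type": self.type_names,
                "mean": diff.mean(axis=0),
                "sd": diff.std(axis=0, ddof=1),
                "pi89_low": lo,
                "pi89_high": hi,
            }
        )

    def fit_report(self) -> dict:
        worst = max(float(np.max(self.rhat(n))) for n in self.hyperparameters)
        return {
            "model": "dirichlet_multinomial",
            "n_individuals": self._X.shape[0],
            "types": self.type_names,
            "covariates": self.covariate_names,
            "worst_hyper_rhat": worst,
            "acceptance_fraction": self.info.get("acceptance_fraction"),
        }


class DirichletMultinomialModel:
    """Repertoire-composition model (see module docstring).

    Parameters
    ----------
    counts : DataFrame
        Individuals x call types (the composition-model view of
        :class:`vocsocial.repertoire.RepertoireTable`). Types with zero
        total count are dropped with a warning.
    covariates : DataFrame, optional
        ``unit_id`` plus covariate columns (continuous columns are
        z-scored; 0/1 columns such as sex are left as-is), aligned to the
        counts index.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        alpha_prior=None,
        theta_rate: float = 0.2,
        beta_sd: float = 0.5,
    ):
        counts = counts.copy()
        zero = counts.columns[(counts.sum(axis=0) == 0).to_numpy()]
        if len(zero):
            warnings.warn(f"dropping call types with zero total count: {list(zero)}")
            counts = counts.drop(columns=zero)
        if counts.shape[0] < 3:
            raise ValueError("need at least 3 individuals")
        if counts.shape[0] < 10:
            warnings.warn("fewer than 10 individuals; composition estimates will be weak")
        self.type_names = list(counts.columns)
        self.individual_ids = list(counts.index)
        self.x_counts = counts.to_numpy(float)
        self.totals = self.x_counts.sum(axis=1)
        K = len(self.type_names)
        if alpha_prior is None:
            alpha_prior = np.r_[DEFAULT_ALPHA_PRIOR, np.full(K - 1, 0.5)]
        self.alpha_prior = np.asarray(alpha_prior, float)
        if self.alpha_prior.size != K:
            raise ValueError("alpha_prior length must match retained call types")
        self.theta_rate = theta_rate
        self.beta_sd = beta_sd
        if covariates is not None:
            cov = covariates.set_index("unit_id").loc[self.individual_ids]
            self.covariate_names = list(cov.columns)
            self.X, self.x_means, self.x_sds = _prepare_design(cov, True)
        else:
            self.covariate_names = []
            self.X = np.zeros((len(self.individual_ids), 0))
            self.x_means, self.x_sds = {}, {}
        self.K = K
        self.p = self.X.shape[1]
        self.ndim = (K - 1) + self.p * K + 1

    # -- parameter packing ---------------------------------------------------
    def _unpack(self, psi):
        """psi (W, ndim) -> log_alpha (W,K), B (W,p,K), theta (W,)."""
        psi = np.atleast_2d(psi)
        K, p = self.K, self.p
        z = np.concatenate([psi[:, : K - 1], np.zeros((psi.shape[0], 1))], axis=1)
        log_alpha = z - logsumexp(z, axis=1, keepdims=True)
        if p:
            B = psi[:, K - 1 : K - 1 + p * K].reshape(psi.shape[0], p, K)
        else:
            B = np.zeros((psi.shape[0], 0, K))
        log_theta = psi[:, -1]
        return log_alpha, B, log_theta

    def log_prob(self, psi, prior_only=False):
        """Vectorised log posterior over an ensemble of parameter vectors."""
        psi = np.atleast_2d(psi)
        W = psi.shape[0]
        out = np.full(W, -np.inf)
        ok = np.all(np.abs(psi) < 30.0, axis=1)
        if not ok.any():
            return out
        log_alpha, B, log_theta = self._unpack(psi[ok])
        theta = np.exp(log_theta)
        # Dirichlet prior on alpha x ALR Jacobian collapses to sum(c*log alpha)
        lp = (self.alpha_prior[None, :] * log_alpha).sum(axis=1)
        if self.p:
            lp -= (B**2).sum(axis=(1, 2)) / (2 * self.beta_sd**2)
        lp += -self.theta_rate * theta + log_theta  # exponential prior + Jacobian
        if not prior_only:
            eta = log_alpha[:, None, :] + np.einsum("ij,wjk->wik", self.X, B)
            eta -= logsumexp(eta, axis=2, keepdims=True)
            A = theta[:, None, None] * np.exp(eta)
            ll = gammaln(theta)[:, None] - gammaln(self.totals[None, :] + theta[:, None])
            ll = ll.sum(axis=1)
            ll += (gammaln(self.x_counts[None] + A) - gammaln(A)).sum(axis=(1, 2))
            lp += ll
        out[ok] = lp
        return out

    def _initial(self, nwalkers, rng):
        pooled = self.x_counts.sum(axis=0) + 0.5
        alpha0 = pooled / pooled.sum()
        z0 = np.log(alpha0[:-1] / alpha0[-1])
        psi0 = np.concatenate([z0, np.zeros(self.p * self.K), [np.log(5.0)]])
        return psi0[None, :] + 0.1 * rng.standard_normal((nwalkers, self.ndim))

    def fit(self, config: SamplerConfig = SamplerConfig(), prior_only: bool = False):
        """Sample the posterior (or the prior alone, for predictive checks)."""
        rng = np.random.default_rng(config.seed)
        nwalkers = config.walkers or max(2 * self.ndim + 2, 32)
        sampler = emcee.EnsembleSampler(
            nwalkers,
            self.ndim,
            self.log_prob,
            kwargs={"prior_only": prior_only},
            vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        state = self._initial(nwalkers, rng)
        sampler.random_state = np.random.RandomState(config.seed)
        sampler.run_mcmc(state, config.warmup + config.draws, progress=False)
        chain = sampler.get_chain(discard=config.warmup)  # (draws, walkers, ndim)
        psi = np.moveaxis(chain, 0, 1)  # (walkers, draws, ndim)
        Wn, D = psi.shape[:2]
        log_alpha, B, log_theta = self._unpack(psi.reshape(-1, self.ndim))
        draws = {
            "alpha": np.exp(log_alpha).reshape(Wn, D, self.K),
            "theta": np.exp(log_theta).reshape(Wn, D),
        }
        if self.p:
            draws["beta"] = B.reshape(Wn, D, self.p * self.K)
        res = DirichletMultinomialResults(
            draws,
            type_names=self.type_names,
            covariate_names=self.covariate_names,
            X=self.X,
            x_means=self.x_means,
            x_sds=self.x_sds,
            hyperparameters=("alpha", "theta") + (("beta",) if self.p else ()),
            config=config,
            info={
                "individual_ids": self.individual_ids,
                "acceptance_fraction": float(sampler.acceptance_fraction.mean()),
                "prior_only": prior_only,
            },
        )
        res.check_convergence()
        return res


def sex_contrast(results: DirichletMultinomialResults, column: str = "sex") -> pd.DataFrame:
    """Functional alias for :meth:`DirichletMultinomialResults.sex_contrast`."""
    return results.sex_contrast(column)
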