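"""Stage-2 models: effect regressions with posterior uncertainty propagated.

The distance models export a posterior mean and standard deviation per unit
(dyad or individual). Stage 2 treats those as noisy measurements of a
latent truth:

``est_mean_k ~ normal(z_k, est_sd_k)``;
``z_k ~ normal(a + x_k' beta [+ u_i + u_j], sigma_resid)``

so that units measured precisely pull the regression harder than units
with wide posteriors. Dyadic outcomes additionally get multi-membership
varying intercepts ``u`` for the two individuals of each dyad.
Setting every ``est_sd`` to zero recovers an ordinary (hierarchical)
regression — a useful limiting-case cross-check.

Information content (per-call amplitude-modulation peak counts) is
modelled hierarchically with individual varying intercepts, either as a
normal model on square-root counts (default) or as a Poisson model with a
log link.

All continuous predictors are z-scored internally; slope posteriors can be
reported on either scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import gammaln

from vocsocial.models.base import MCMCResults, SamplerConfig, slice_sample
from vocsocial.models.distance import _chain_rng, _sample_scale

__all__ = [
    "MeasurementErrorRegression",
    "MeasurementErrorResults",
    "InformationContentModel",
    "InformationContentResults",
]


def _prepare_design(X: pd.DataFrame, standardize: bool):
    """Z-score continuous columns; leave 0/1 columns alone."""
    means, sds = {}, {}
    W = np.empty((len(X), X.shape[1]))
    for k, col in enumerate(X.columns):
        v = X[col].to_numpy(float)
        uniq = np.unique(v[np.isfinite(v)])
        is_binary = uniq.size <= 2 and np.all(np.isin(uniq, (0.0, 1.0)))
        if standardize and not is_binary:
            m, s = v.mean(), v.std()
            if s == 0:
                raise ValueError(f"predictor {col!r} is constant")
            means[col], sds[col] = m, s
            W[:, k] = (v - m) / s
        else:
            means[col], sds[col] = 0.0, 1.0
            W[:, k] = v
    return W, means, sds


class MeasurementErrorResults(MCMCResults):
    """Posterior for a stage-2 measurement-error regression."""

    def __init__(self, draws, predictor_names, x_means, x_sds, y_scale=1.0, **kw):
        super().__init__(draws, **kw)
        self.predictor_names = list(predictor_names)
        self._x_means = x_means
        self._x_sds = x_sds
        self._y_scale = y_scale

    def slope_estimates(self, scale: str = "standardized") -> pd.DataFrame:
        """Per-predictor slope: mean, sd, 89% PI, Rhat.

        ``scale="original"`` undoes the internal z-scoring of outcome and
        predictors (slope per raw predictor unit on the raw outcome scale).
        """
        tab = self.posterior_table("beta", self.predictor_names)
        tab = tab.rename(columns={"unit_id": "predictor"})
        if scale == "original":
            f = np.array([self._y_scale / self._x_sds[p] for p in self.predictor_names])
            for col in ("mean", "sd", "pi89_low", "pi89_high"):
                tab[col] = tab[col] * f
        return tab

    def fit_report(self) -> dict:
        worst = max(float(np.max(self.rhat(n))) for n in self.hyperparameters)
        return {
            "model": "measurement_error_regression",
            "n_units": self.info.get("n_units"),
            "predictors": self.predictor_names,
            "worst_hyper_rhat": worst,
            "seed": self.config.seed if self.config else None,
        }


class MeasurementErrorRegression:
    """Latent-truth regression of exported posterior summaries on predictors.

    Parameters
    ----------
    outcomes : DataFrame
        Columns ``unit_id``, ``est_mean``, ``est_sd`` (sd >= 0; zero pins
        the latent value to the estimate).
    predictors : DataFrame
        ``unit_id`` plus one column per predictor; merged on unit_id.
        Rows with missing values are dropped (complete cases); an
        all-missing predictor raises, naming the variable.
    formula : sequence of str
        Predictor columns to include.
    members : DataFrame, optional
        ``unit_id``, ``id_i``, ``id_j`` — enables multi-membership varying
        intercepts for dyadic outcomes. Dyads whose members cannot be
        resolved are dropped with a report.
    intercept_prior : (mean, sd)
        normal prior on the intercept; (0, 0.5) default, (1, 1) is the
        convention for repertoire-entropy outcomes.
    """

    def __init__(
        self,
        outcomes: pd.DataFrame,
        predictors: pd.DataFrame,
        formula,
        members: pd.DataFrame | None = None,
        intercept_prior=(0.0, 0.5),
        slope_prior_sd: float = 0.5,
        sigma_rate: float = 2.0,
        sigma_member_rate: float = 2.0,
        standardize: bool = True,
    ):
        formula = list(formula)
        missing_cols = [c for c in formula if c not in predictors.columns]
        if missing_cols:
            raise ValueError(f"predictors missing from table: {missing_cols}")
        for c in formula:
            if predictors[c].isna().all():
                raise ValueError(f"predictor {c!r} has no observed values")
        df = outcomes.merge(predictors[["unit_id", *formula]], on="unit_id", how="inner")
        if members is not None:
            df = df.drop(columns=[c for c in ("id_i", "id_j") if c in df.columns])
            df = df.merge(members[["unit_id", "id_i", "id_j"]], on="unit_id", how="left")
            n_bad = int(df[["id_i", "id_j"]].isna().any(axis=1).sum())
            if n_bad:
                import warnings

                warnings.warn(f"dropping {n_bad} dyads with unresolved members")
                df = df.dropna(subset=["id_i", "id_j"])
        df = df.dropna(subset=["est_mean", "est_sd", *formula]).reset_index(drop=True)
        if len(df) < len(formula) + 3:
            raise ValueError("too few complete cases to fit")
        self.unit_ids = df["unit_id"].to_numpy()
        self.m = df["est_mean"].to_numpy(float)
        self.sd = df["est_sd"].to_numpy(float)
        if (self.sd < 0).any():
            raise ValueError("negative est_sd")
        # z-score the outcome so priors are weakly informative on the model
        # scale; est_sd scales with it (a pure relabelling of units)
        self.y_shift_ = float(self.m.mean()) if standardize else 0.0
        y_sd = float(self.m.std()) if standardize else 1.0
        self.y_scale_ = y_sd if y_sd > 0 else 1.0
        self.m = (self.m - self.y_shift_) / self.y_scale_
        self.sd = self.sd / self.y_scale_
        self.formula = formula
        Xs, self.x_means, self.x_sds = _prepare_design(df[formula], standardize)
        self.W = np.column_stack([np.ones(len(df)), Xs])
        self.intercept_prior = intercept_prior
        self.slope_prior_sd = slope_prior_sd
        self.sigma_rate = sigma_rate
        self.sigma_member_rate = sigma_member_rate
        self.members = None
        if members is not None:
            mem_ids = pd.concat([df["id_i"], df["id_j"]])
            self.member_ids = np.unique(mem_ids)
            pos = {b: k for k, b in enumerate(self.member_ids)}
            self.m1 = df["id_i"].map(pos).to_numpy()
            self.m2 = df["id_j"].map(pos).to_numpy()
            n_m = len(self.member_ids)
            G = np.zeros((n_m, n_m))
            np.add.at(G, (self.m1, self.m1), 1.0)
            np.add.at(G, (self.m2, self.m2), 1.0)
            np.add.at(G, (self.m1, self.m2), 1.0)
            np.add.at(G, (self.m2, self.m1), 1.0)
            self._gram_m = G
            self.members = True

    def fit(self, config: SamplerConfig = SamplerConfig()) -> MeasurementErrorResults:
        n = len(self.m)
        p = self.W.shape[1]
        prior_prec = np.ones(p) / self.slope_prior_sd**2
        prior_prec[0] = 1.0 / self.intercept_prior[1] ** 2
        prior_mean = np.zeros(p)
        prior_mean[0] = self.intercept_prior[0]
        WtW = self.W.T @ self.W
        exact = self.sd == 0.0
        sd2 = np.where(exact, 1.0, self.sd**2)
        keep = config.draws
        n_m = len(self.member_ids) if self.members else 0
        store = {
            "intercept": np.empty((config.chains, keep)),
            "beta": np.empty((config.chains, keep, p - 1)),
            "sigma_resid": np.empty((config.chains, keep)),
        }
        if self.members:
            store["sigma_member"] = np.empty((config.chains, keep))
            eye_m = np.eye(n_m)

        for chain in range(config.chains):
            rng = _chain_rng(config.seed, chain)
            sigma = max(rng.exponential(1 / self.sigma_rate), 0.02)
            sigma_u = max(rng.exponential(1 / self.sigma_member_rate), 0.02)
            beta = np.zeros(p)
            beta[0] = self.m.mean()
            u = np.zeros(n_m) if self.members else None
            z = self.m.copy()

            for it in range(config.warmup + keep):
                mu = self.W @ beta
                if self.members:
                    mu = mu + u[self.m1] + u[self.m2]
                # latent truths
                prec_z = 1.0 / sd2 + 1.0 / sigma**2
                mean_z = (self.m / sd2 + mu / sigma**2) / prec_z
                z = mean_z + rng.standard_normal(n) / np.sqrt(prec_z)
                z[exact] = self.m[exact]

                # regression coefficients (joint conjugate)
                target = z - (u[self.m1] + u[self.m2] if self.members else 0.0)
                lam = WtW / sigma**2 + np.diag(prior_prec)
                rhs = self.W.T @ target / sigma**2 + prior_prec * prior_mean
                L = cholesky(lam, lower=True)
                beta = cho_solve((L, True), rhs) + solve_triangular(
                    L.T, rng.standard_normal(p), lower=False
                )

                # multi-membership varying intercepts
                if self.members:
                    resid = z - self.W @ beta
                    b = np.bincount(self.m1, weights=resid, minlength=n_m)
                    b += np.bincount(self.m2, weights=resid, minlength=n_m)
                    lam_u = self._gram_m / sigma**2 + eye_m / sigma_u**2
                    Lu = cholesky(lam_u, lower=True)
                    u = cho_solve((Lu, True), b / sigma**2) + solve_triangular(
                        Lu.T, rng.standard_normal(n_m), lower=False
                    )
                    sigma_u = _sample_scale((u**2).sum(), n_m, self.sigma_member_rate, sigma_u, rng)
                    resid = resid - u[self.m1] - u[self.m2]
                else:
                    resid = z - self.W @ beta
                sigma = _sample_scale((resid**2).sum(), n, self.sigma_rate, sigma, rng)

                if it >= config.warmup:
                    k = it - config.warmup
                    store["intercept"][chain, k] = beta[0]
                    store["beta"][chain, k] = beta[1:]
                    store["sigma_resid"][chain, k] = sigma
                    if self.members:
                        store["sigma_member"][chain, k] = sigma_u

        hypers = ["intercept", "sigma_resid"] + (["sigma_member"] if self.members else [])
        res = MeasurementErrorResults(
            store,
            predictor_names=self.formula,
            x_means=self.x_means,
            x_sds=self.x_sds,
            y_scale=self.y_scale_,
            hyperparameters=tuple(hypers) + ("beta",),
            config=config,
            info={"n_units": n},
        )
        res.check_convergence()
        return res


class InformationContentResults(MCMCResults):
    """Posterior for the information-content (AM-peak) model."""

    def __init__(self, draws, predictor_names, x_means, x_sds, **kw):
        super().__init__(draws, **kw)
        self.predictor_names = list(predictor_names)
        self._x_means = x_means
        self._x_sds = x_sds
        self._y_scale = 1.0  # counts are modelled on their own scale

    slope_estimates = MeasurementErrorResults.slope_estimates

    def sigma_ind(self) -> float:
        """Posterior mean of the between-individual intercept sd."""
        return float(self.mean("sigma_ind"))

    def fit_report(self) -> dict:
        worst = max(float(np.max(self.rhat(n))) for n in self.hyperparameters)
        return {
            "model": "information_content",
            "likelihood": self.info.get("likelihood"),
            "predictors": self.predictor_names,
            "sigma_ind_mean": self.sigma_ind(),
            "worst_hyper_rhat": worst,
        }


class InformationContentModel:
    """Hierarchical model of per-call amplitude-modulation peak counts.

    ``sqrt_normal`` (default): normal likelihood on square-root counts with
    individual varying intercepts. ``poisson``: log-link Poisson, sampled
    by slice-within-Gibbs (coefficients) and adaptive Metropolis
    (intercepts). Individuals with a single call are retained; they inform
    only the intercept distribution.

    Parameters
    ----------
    peaks : DataFrame
        Columns ``count`` (>= 0) and ``individual_id``, one row per call.
    predictors : DataFrame
        ``unit_id`` plus predictor columns, one row per individual.
    formula : sequence of str
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        predictors: pd.DataFrame,
        formula,
        likelihood: str = "sqrt_normal",
        intercept_prior_sd: float = 2.0,
        slope_prior_sd: float = 0.5,
        sigma_rate: float = 2.0,
        sigma_ind_rate: float = 2.0,
    ):
        if likelihood not in ("sqrt_normal", "poisson"):
            raise ValueError(f"unknown likelihood {likelihood!r}")
        formula = list(formula)
        y = peaks["count"].to_numpy(float)
        if (y < 0).any() or not np.isfinite(y).all():
            raise ValueError("peak counts must be finite and nonnegative")
        pred = predictors.dropna(subset=formula)
        df = peaks.merge(
            pred[["unit_id", *formula]], left_on="individual_id", right_on="unit_id", how="inner"
        ).reset_index(drop=True)
        if df.empty:
            raise ValueError("no calls with complete predictor data")
        self.likelihood = likelihood
        self.y = df["count"].to_numpy(float)
        self.individual_ids, self.ind_idx = np.unique(df["individual_id"], return_inverse=True)
        Xs, self.x_means, self.x_sds = _prepare_design(df[formula], True)
        self.W = np.column_stack([np.ones(len(df)), Xs])
        self.formula = formula
        self.intercept_prior_sd = intercept_prior_sd
        self.slope_prior_sd = slope_prior_sd
        self.sigma_rate = sigma_rate
        self.sigma_ind_rate = sigma_ind_rate

    def fit(self, config: SamplerConfig = SamplerConfig()) -> InformationContentResults:
        if self.likelihood == "sqrt_normal":
            store, hypers = self._fit_sqrt_normal(config)
        else:
            store, hypers = self._fit_poisson(config)
        res = InformationContentResults(
            store,
            predictor_names=self.formula,
            x_means=self.x_means,
            x_sds=self.x_sds,
            hyperparameters=hypers,
            config=config,
            info={"likelihood": self.likelihood, "n_calls": len(self.y)},
        )
        res.check_convergence()
        return res

    def _fit_sqrt_normal(self, config):
        t = np.sqrt(self.y)
        n, p = self.W.shape
        n_i = len(self.individual_ids)
        n_per = np.bincount(self.ind_idx, minlength=n_i)
        prior_prec = np.ones(p) / self.slope_prior_sd**2
        prior_prec[0] = 1.0 / self.intercept_prior_sd**2
        WtW = self.W.T @ self.W
        keep = config.draws
        store = {
            "intercept": np.empty((config.chains, keep)),
            "beta": np.empty((config.chains, keep, p - 1)),
            "sigma": np.empty((config.chains, keep)),
            "sigma_ind": np.empty((config.chains, keep)),
        }
        for chain in range(config.chains):
            rng = _chain_rng(config.seed, chain)
            sigma = max(rng.exponential(1 / self.sigma_rate), 0.02)
            sigma_i = max(rng.exponential(1 / self.sigma_ind_rate), 0.02)
            beta = np.zeros(p)
            beta[0] = t.mean()
            u = np.zeros(n_i)
            for it in range(config.warmup + keep):
                resid = t - u[self.ind_idx]
                lam = WtW / sigma**2 + np.diag(prior_prec)
                rhs = self.W.T @ resid / sigma**2
                L = cholesky(lam, lower=True)
                beta = cho_solve((L, True), rhs) + solve_triangular(
                    L.T, rng.standard_normal(p), lower=False
                )
                resid = t - self.W @ beta
                s_i = np.bincount(self.ind_idx, weights=resid, minlength=n_i)
                prec = n_per / sigma**2 + 1.0 / sigma_i**2
                u = s_i / sigma**2 / prec + rng.standard_normal(n_i) / np.sqrt(prec)
                resid = resid - u[self.ind_idx]
                sigma = _sample_scale((resid**2).sum(), n, self.sigma_rate, sigma, rng)
                sigma_i = _sample_scale((u**2).sum(), n_i, self.sigma_ind_rate, sigma_i, rng)
                if it >= config.warmup:
                    k = it - config.warmup
                    store["intercept"][chain, k] = beta[0]
                    store["beta"][chain, k] = beta[1:]
                    store["sigma"][chain, k] = sigma
                    store["sigma_ind"][chain, k] = sigma_i
        return store, ("intercept", "beta", "sigma", "sigma_ind")

    def _fit_poisson(self, config):
        y = self.y
        n, p = self.W.shape
        n_i = len(self.individual_ids)
        prior_sd = np.full(p, self.slope_prior_sd)
        prior_sd[0] = self.intercept_prior_sd
        keep = config.draws
        store = {
            "intercept": np.empty((config.chains, keep)),
            "beta": np.empty((config.chains, keep, p - 1)),
            "sigma_ind": np.empty((config.chains, keep)),
        }
        y_sum_i = np.bincount(self.ind_idx, weights=y, minlength=n_i)

        for chain in range(config.chains):
            rng = _chain_rng(config.seed, chain)
            sigma_i = max(rng.exponential(1 / self.sigma_ind_rate), 0.02)
            beta = np.zeros(p)
            beta[0] = np.log(max(y.mean(), 0.1))
            u = np.zeros(n_i)
            step = np.full(n_i, 0.3)

            for it in range(config.warmup + keep):
                # coefficients: univariate slice sampling
                for j in range(p):
                    wj = self.W[:, j]
                    eta_rest = self.W @ beta - wj * beta[j] + u[self.ind_idx]

                    def logp(bj, wj=wj, eta_rest=eta_rest, j=j):
                        eta = eta_rest + wj * bj
                        return float((y * eta - np.exp(eta)).sum()) - bj**2 / (2 * prior_sd[j] ** 2)

                    beta[j] = slice_sample(logp, beta[j], rng, w=0.5)

                # individual intercepts: vectorised Metropolis
                eta0 = self.W @ beta
                prop = u + step * rng.standard_normal(n_i)
                ll_cur = y_sum_i * u - np.bincount(
                    self.ind_idx, weights=np.exp(eta0 + u[self.ind_idx]), minlength=n_i
                )
                ll_prop = y_sum_i * prop - np.bincount(
                    self.ind_idx, weights=np.exp(eta0 + prop[self.ind_idx]), minlength=n_i
                )
                log_acc = ll_prop - ll_cur - (prop**2 - u**2) / (2 * sigma_i**2)
                accept = np.log(rng.uniform(size=n_i)) < log_acc
                u = np.where(accept, prop, u)
                if it < config.warmup:
                    step *= np.where(accept, 1.05, 0.96)
                    step = np.clip(step, 0.01, 2.0)

                sigma_i = _sample_scale((u**2).sum(), n_i, self.sigma_ind_rate, sigma_i, rng)

                if it >= config.warmup:
                    k = it - config.warmup
                    store["intercept"][chain, k] = beta[0]
                    store["beta"][chain, k] = beta[1:]
                    store["sigma_ind"][chain, k] = sigma_i
        return store, ("intercept", "beta", "sigma_ind")
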