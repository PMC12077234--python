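"""Shared MCMC infrastructure: sampler configuration, slice sampling and
posterior-results containers.

All fitted models in :mod:`vocsocial.models` return a subclass of
:class:`MCMCResults`, which stores raw draws with shape
``(chains, draws[, k])`` and provides equal-tailed 89% posterior intervals,
split-Rhat / effective-sample-size diagnostics (via arviz) and tidy summary
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "SamplerConfig",
    "ConvergenceWarning",
    "MCMCResults",
    "slice_sample",
    "PI_PROB",
]

#: probability mass of the equal-tailed posterior interval reported throughout
PI_PROB = 0.89


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when Rhat exceeds the convergence gate."""


@dataclass(frozen=True)
class SamplerConfig:
    """Settings for MCMC sampling.

    Parameters
    ----------
    chains : int
        Number of independent chains (Gibbs samplers) or pseudo-chains
        (groups of ensemble walkers) used for split-Rhat.
    warmup, draws : int
        Iterations discarded / retained per chain. For ensemble samplers
        these count ensemble steps.
    seed : int
        Root seed; every chain derives its own stream from it.
    walkers : int or None
        Ensemble size for emcee-based models; ``None`` picks
        ``max(2 * ndim + 2, 32)``.
    rhat_threshold : float
        Convergence gate on hyperparameters; a violation raises a
        :class:`ConvergenceWarning`, never a silent pass.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    walkers: int | None = None
    rhat_threshold: float = 1.01

    def with_seed(self, seed: int) -> "SamplerConfig":
        return replace(self, seed=int(seed))


def slice_sample(logpdf, x0, rng, w=1.0, max_steps=100):
    """One update of a univariate stepping-out/shrinkage slice sampler.

    Parameters
    ----------
    logpdf : callable
        Log density (up to a constant) of the target.
    x0 : float
        Current value; must have finite density.
    rng : numpy.random.Generator
    w : float
        Initial bracket width for stepping out.

    Returns
    -------
    float
        The new state.
    """
    f0 = logpdf(x0)
    if not np.isfinite(f0):
        raise ValueError("slice_sample started from a zero-density point")
    log_y = f0 + np.log(rng.uniform())
    # step out
    u = rng.uniform()
    lo = x0 - w * u
    hi = lo + w
    j = int(max_steps * rng.uniform())
    k = max_steps - 1 - j
    while j > 0 and logpdf(lo) > log_y:
        lo -= w
        j -= 1
    while k > 0 and logpdf(hi) > log_y:
        hi += w
        k -= 1
    # shrinkage
    for _ in range(1000):
        x1 = rng.uniform(lo, hi)
        if logpdf(x1) > log_y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # pathological target; keep current state


def _as_dataset(draws: dict[str, np.ndarray]):
    return az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})


class MCMCResults:
    """Container for posterior draws plus diagnostics.

    Parameters
    ----------
    draws : dict
        Maps parameter name to an array of shape ``(chains, draws)`` for
        scalars or ``(chains, draws, k)`` for vector parameters.
    hyperparameters : sequence of str
        Names whose Rhat is checked against the convergence gate.
    config : SamplerConfig
    """

    def __init__(self, draws, hyperparameters=(), config=None, info=None):
        self.draws = {k: np.asarray(v) for k, v in draws.items()}
        self.hyperparameters = tuple(hyperparameters)
        self.config = config
        self.info = dict(info or {})
        self._rhat_cache: dict[str, np.ndarray] = {}

    # -- accessors ---------------------------------------------------------
    def stacked(self, name):
        """Draws for `name` pooled over chains: shape ``(n_total[, k])``."""
        x = self.draws[name]
        return x.reshape(-1, *x.shape[2:])

    def mean(self, name):
        return self.stacked(name).mean(axis=0)

    def sd(self, name):
        return self.stacked(name).std(axis=0, ddof=1)

    def interval(self, name, prob=PI_PROB):
        """Equal-tailed posterior interval (default 89%)."""
        lo = (1.0 - prob) / 2.0
        x = self.stacked(name)
        return np.quantile(x, [lo, 1.0 - lo], axis=0)

    # -- diagnostics -------------------------------------------------------
    def rhat(self, name):
        if name not in self._rhat_cache:
            ds = _as_dataset({name: self.draws[name]})
            self._rhat_cache[name] = np.asarray(az.rhat(ds)[name])
        return self._rhat_cache[name]

    def ess(self, name):
        ds = _as_dataset({name: self.draws[name]})
        return np.asarray(az.ess(ds)[name])

    def check_convergence(self, threshold=None):
        """Check split-Rhat of all hyperparameters against the gate.

        Returns the worst Rhat and issues a :class:`ConvergenceWarning`
        when the gate is exceeded.
        """
        threshold = threshold or (self.config.rhat_threshold if self.config else 1.01)
        worst = 0.0
        for name in self.hyperparameters:
            worst = max(worst, float(np.max(self.rhat(name))))
        if worst >= threshold:
            warnings.warn(
                f"worst hyperparameter Rhat {worst:.4f} >= {threshold}; "
                "increase warmup/draws before trusting the posterior",
                ConvergenceWarning,
                stacklevel=2,
            )
        return worst

    # -- tables ------------------------------------------------------------
    def summary(self, var_names=None) -> pd.DataFrame:
        """Tidy summary: mean, sd, 89% interval, Rhat, bulk ESS per scalar."""
        var_names = list(var_names) if var_names is not None else list(self.draws)
        rows = []
        for name in var_names:
            x = self.stacked(name)
            rh = np.atleast_1d(self.rhat(name))
            es = np.atleast_1d(self.ess(name))
            if x.ndim == 1:
                x = x[:, None]
            lo, hi = np.quantile(x, [(1 - PI_PROB) / 2, 1 - (1 - PI_PROB) / 2], axis=0)
            for k in range(x.shape[1]):
                label = name if x.shape[1] == 1 else f"{name}[{k}]"
                rows.append(
                    {
                        "parameter": label,
                        "mean": x[:, k].mean(),
                        "sd": x[:, k].std(ddof=1),
                        "pi89_low": lo[k],
                        "pi89_high": hi[k],
                        "rhat": rh[min(k, rh.size - 1)],
                        "ess_bulk": es[min(k, es.size - 1)],
                    }
                )
        return pd.DataFrame(rows)

    def posterior_table(self, name, unit_ids, scale=1.0, shift=0.0) -> pd.DataFrame:
        """Per-unit posterior export: mean, sd, 89% PI, Rhat.

        `scale`/`shift` undo any standardisation applied before fitting
        (exported value = scale * draw + shift; sd scales accordingly).
        """
        x = self.stacked(name) * scale + shift
        lo, hi = np.quantile(x, [(1 - PI_PROB) / 2, 1 - (1 - PI_PROB) / 2], axis=0)
        rh = np.atleast_1d(self.rhat(name))
        if rh.size == 1:
            rh = np.repeat(rh, x.shape[1])
        return pd.DataFrame(
            {
                "unit_id": list(unit_ids),
                "mean": x.mean(axis=0),
                "sd": x.std(axis=0, ddof=1),
                "pi89_low": lo,
                "pi89_high": hi,
                "rhat": rh,
            }
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        shapes = {k: v.shape for k, v in self.draws.items()}
        return f"{type(self).__name__}({shapes})"
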