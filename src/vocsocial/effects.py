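"""Total and direct causal effects via back-door adjustment on shipped DAGs.

The candidate drivers of call similarity, diversity and information
content are entangled (age affects chamber size, nesting location affects
network position, ...), so each effect is estimated twice from an explicit
causal diagram:

* **total** effect — adjust only for confounders that open back-door
  paths into the exposure (the exposure's parents in the DAG);
* **direct** effect — additionally condition on the mediators lying on
  indirect exposure -> outcome paths, closing any back-door paths that
  conditioning on a mediator opens (the mediators' parents).

DAGs are data, not code: the package ships edge lists for the three
outcome families plus a registry of named effect models (exposure,
covariate set, direction of the original expectation). Custom DAGs can be
supplied as edge lists.

The registry's covariate sets are the published model specifications; for
most rows they coincide with what the back-door algorithm derives from
the shipped DAGs (see docs/methods.md for the two rows where the printed
set includes extra precision covariates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd

from vocsocial.models.base import SamplerConfig
from vocsocial.models.measurement import InformationContentModel, MeasurementErrorRegression

__all__ = [
    "CausalDAG",
    "EffectSpec",
    "load_dag",
    "load_registry",
    "build_adjustment",
    "fit_individual_effect_model",
    "fit_dyadic_effect_model",
    "fit_information_model",
    "effect_row",
    "forest_plot",
]


class CausalDAG:
    """A directed acyclic graph of assumed causal effects."""

    def __init__(self, edges, outcome: str, name: str = ""):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"causal graph contains a cycle: {cycle}")
        self.graph = g
        self.outcome = outcome
        self.name = name

    def mediators(self, exposure, outcome=None):
        """Nodes on directed exposure -> outcome paths (excluding both)."""
        outcome = outcome or self.outcome
        med = set()
        for path in nx.all_simple_paths(self.graph, exposure, outcome):
            med.update(path[1:-1])
        return med

    def adjustment_set(self, exposure, kind: str = "total", outcome=None):
        """Back-door adjustment set for the exposure -> outcome effect.

        ``total``: the exposure's parents (a valid back-door set — parents
        can never be descendants of the exposure). ``direct``: parents
        plus the mediators on indirect paths, plus the mediators' own
        parents (conditioning on a mediator opens back-door paths through
        them; a mediator's parent is either itself a mediator or a
        non-descendant of the exposure, so the closure is safe).
        """
        outcome = outcome or self.outcome
        if exposure not in self.graph:
            raise ValueError(f"exposure {exposure!r} absent from DAG {self.name!r}")
        if outcome not in self.graph:
            raise ValueError(f"outcome {outcome!r} absent from DAG {self.name!r}")
        if kind not in ("total", "direct"):
            raise ValueError(f"kind must be 'total' or 'direct', got {kind!r}")
        adj = set(self.graph.predecessors(exposure))
        if kind == "direct":
            med = self.mediators(exposure, outcome)
            adj |= med
            frontier = set(med)
            while frontier:
                new = set()
                for m in frontier:
                    new.update(self.graph.predecessors(m))
                new -= adj | {exposure, outcome}
                adj |= new
                frontier = new & nx.descendants(self.graph, exposure)
        adj.discard(outcome)
        return adj


@dataclass
class EffectSpec:
    """One effect model: outcome, exposure, kind, and its adjustment set."""

    outcome: str
    exposure: str
    kind: str = "total"
    adjustment: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.exposure in self.adjustment:
            raise ValueError("exposure cannot appear in its own adjustment set")

    @property
    def formula(self):
        """Predictor list for the regression: exposure first, then adjustment."""
        return [self.exposure, *sorted(self.adjustment)]


def _data_json(fname):
    with resources.files("vocsocial.data").joinpath(fname).open() as fh:
        return json.load(fh)


def load_dag(name: str) -> CausalDAG:
    """Load one of the shipped DAGs: similarity, diversity, information."""
    dags = _data_json("dags.json")
    if name not in dags:
        raise KeyError(f"no shipped DAG named {name!r}; have {sorted(dags)}")
    spec = dags[name]
    return CausalDAG(spec["edges"], outcome=spec["outcome"], name=name)


def load_registry() -> pd.DataFrame:
    """The registry of published effect models (one row per exposure)."""
    return pd.DataFrame(_data_json("registry.json"))


def build_adjustment(spec: EffectSpec, dag: CausalDAG) -> EffectSpec:
    """Fill in a spec's adjustment set from the DAG via the back-door rule.

    The requested outcome label may differ from the DAG's outcome node (e.g.
    repertoire entropy reuses the diversity DAG); the graph's own outcome
    node is used for path analysis.
    """
    outcome_node = spec.outcome if spec.outcome in dag.graph else dag.outcome
    adj = dag.adjustment_set(spec.exposure, kind=spec.kind, outcome=outcome_node)
    return EffectSpec(spec.outcome, spec.exposure, spec.kind, tuple(sorted(adj)))


def fit_individual_effect_model(
    outcomes: pd.DataFrame,
    predictors: pd.DataFrame,
    formula,
    config: SamplerConfig = SamplerConfig(),
    intercept_prior=(0.0, 0.5),
):
    """Individual-level measurement-error regression (diversity, entropy).

    `outcomes` carries ``unit_id``, ``est_mean``, ``est_sd``; use
    ``intercept_prior=(1, 1)`` for repertoire-entropy outcomes.
    """
    model = MeasurementErrorRegression(
        outcomes, predictors, formula, intercept_prior=intercept_prior
    )
    return model.fit(config)


def fit_dyadic_effect_model(
    dyad_outcomes: pd.DataFrame,
    predictors: pd.DataFrame,
    formula,
    config: SamplerConfig = SamplerConfig(),
):
    """Dyad-level regression with multi-membership varying intercepts.

    Both tables are keyed by ``unit_id`` (the dyad id); `predictors` (or
    `dyad_outcomes`) must carry ``id_i``/``id_j`` so each dyad's two
    members get varying intercepts.
    """
    members = predictors if {"id_i", "id_j"}.issubset(predictors.columns) else dyad_outcomes
    model = MeasurementErrorRegression(
        dyad_outcomes,
        predictors,
        formula,
        members=members[["unit_id", "id_i", "id_j"]],
    )
    return model.fit(config)


def fit_information_model(
    peaks: pd.DataFrame,
    predictors: pd.DataFrame,
    formula,
    config: SamplerConfig = SamplerConfig(),
    likelihood: str = "sqrt_normal",
):
    """Hierarchical model of AM-peak counts on individual-level predictors."""
    model = InformationContentModel(peaks, predictors, formula, likelihood=likelihood)
    return model.fit(config)


def effect_row(spec: EffectSpec, results, n: int | None = None) -> dict:
    """Tidy one fitted effect into a table row (exposure slope only)."""
    slopes = results.slope_estimates()
    row = slopes[slopes["predictor"] == spec.exposure].iloc[0]
    return {
        "outcome": spec.outcome,
        "exposure": spec.exposure,
        "kind": spec.kind,
        "mean": row["mean"],
        "pi89_low": row["pi89_low"],
        "pi89_high": row["pi89_high"],
        "n": n if n is not None else results.info.get("n_units"),
    }


def forest_plot(effect_table: pd.DataFrame, path=None, ax=None):
    """Forest plot of effect posteriors (dot = mean, line = 89% PI)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 0.5 * max(4, len(effect_table))))
    else:
        fig = ax.figure
    labels = [
        f"{r.outcome}: {r.exposure} ({r.kind})" for r in effect_table.itertuples(index=False)
    ]
    ypos = range(len(effect_table))[::-1]
    ax.hlines(ypos, effect_table["pi89_low"], effect_table["pi89_high"], color="0.3")
    ax.plot(effect_table["mean"], ypos, "o", color="0.1")
    ax.axvline(0.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(labels)
    ax.set_xlabel("effect (89% posterior interval)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
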