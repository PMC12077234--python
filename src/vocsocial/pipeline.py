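"""End-to-end orchestration: simulate -> networks -> distances -> fits.

A single validated :class:`PipelineConfig` drives every stage with a fixed
seed; the artifact directory it produces is fully reproducible from
(inputs, seed) and contains only delimited text and JSON:

::

    outdir/
      inputs/       generated (or copied-through) observation tables
      networks/     edge lists per layer + node_metrics.tsv
      distances/    between.tsv / within.tsv distance observations
      posteriors/   per-dyad and per-individual posterior summaries
      effects/      tidy effect table (outcome, exposure, kind, ...)
      repertoire/   entropy per individual + sex-contrast table
      report.json   stage log, Rhat ranges, config hash, seed

Stages communicate only through these file contracts (plus in-memory
hand-off within one `run` call for speed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from vocsocial import acoustics, networks, repertoire, synthdata
from vocsocial.effects import (
    EffectSpec,
    build_adjustment,
    effect_row,
    fit_dyadic_effect_model,
    fit_individual_effect_model,
    fit_information_model,
    load_dag,
    load_registry,
)
from vocsocial.models import (
    DirichletMultinomialModel,
    DyadicDistanceModel,
    SamplerConfig,
    WithinIndividualDistanceModel,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "networks",
    "distances",
    "fit-dyadic",
    "fit-diversity",
    "fit-information",
    "fit-repertoire",
    "fit-effects",
)

#: DAG node standing in for the foraging/multiplex position metrics
POSITION_METRICS = ("degree", "eigenvector", "betweenness", "versatility")


class SamplerSettings(BaseModel):
    chains: int = 4
    warmup: int = 600
    draws: int = 600
    dm_warmup: int = 2000
    dm_draws: int = 800


class Thresholds(BaseModel):
    min_calls: int = 30
    min_height: float = 30.0
    max_pairs_per_dyad: int | None = 3


class EffectRequest(BaseModel):
    outcome: str
    exposure: str
    kind: str = "total"


DEFAULT_EFFECTS = (
    EffectRequest(outcome="similarity", exposure="tolerance", kind="total"),
    EffectRequest(outcome="similarity", exposure="relatedness", kind="total"),
    EffectRequest(outcome="diversity", exposure="chamber_size", kind="total"),
    EffectRequest(outcome="diversity", exposure="age", kind="direct"),
    EffectRequest(outcome="entropy", exposure="sex", kind="direct"),
    EffectRequest(outcome="entropy", exposure="tree_size", kind="total"),
)


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "artifacts"
    stages: tuple[str, ...] = ALL_STAGES
    input_dir: str | None = None  # read tables instead of simulating
    population: synthdata.PopulationConfig = Field(default_factory=synthdata.PopulationConfig)
    observations: synthdata.ObservationConfig = Field(default_factory=synthdata.ObservationConfig)
    calls: synthdata.CallConfig = Field(default_factory=synthdata.CallConfig)
    similarity_effect: float = 0.0
    sampler: SamplerSettings = Field(default_factory=SamplerSettings)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    effects: tuple[EffectRequest, ...] = DEFAULT_EFFECTS
    write_traces: bool = False
    information_likelihood: str = "sqrt_normal"

    def config_hash(self) -> str:
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _tsv(df: pd.DataFrame, path: Path, float_format="%.10g"):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def _sampler_config(settings: SamplerSettings, seed: int) -> SamplerConfig:
    return SamplerConfig(chains=settings.chains, warmup=settings.warmup, draws=settings.draws, seed=seed)


def _load_inputs(input_dir: Path):
    req = ["individuals.tsv", "nest_sites.tsv", "sightings.tsv", "interactions.tsv", "calls.tsv"]
    missing = [f for f in req if not (input_dir / f).exists()]
    if missing:
        raise StageError("simulate", f"input tables missing from {input_dir}: {missing}")
    tabs = {f.split(".")[0]: pd.read_csv(input_dir / f, sep="\t") for f in req}
    rel_path = input_dir / "relatedness.tsv"
    tabs["relatedness"] = pd.read_csv(rel_path, sep="\t", index_col=0) if rel_path.exists() else None
    traces = {}
    tdir = input_dir / "traces"
    needed = set(tabs["calls"]["recording_id"])
    if tdir.exists():
        for rec in sorted(needed):
            f = tdir / f"{rec}.tsv"
            if not f.exists():
                continue
            df = pd.read_csv(f, sep="\t")
            for cid, grp in df.groupby("call_id"):
                traces[cid] = grp["f0_hz"].to_numpy()
    missing_recs = sorted(needed - {r for r in needed if all(
        cid in traces for cid in tabs["calls"].loc[tabs["calls"].recording_id == r, "call_id"])})
    if missing_recs:
        raise StageError("distances", f"missing trace files for recordings: {missing_recs[:10]}")
    return tabs, traces


def run(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "fits": {},
    }
    state: dict = {}

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise StageError(stage, f"unknown stage; valid: {ALL_STAGES}")
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, state, out, report)
        except StageError:
            raise
        except Exception as exc:  # surface stage + cause
            raise StageError(stage, str(exc)) from exc
        report["stages"][stage] = "ok"
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, out, report):
    if config.input_dir is not None:
        tabs, traces = _load_inputs(Path(config.input_dir))
        state.update(tabs)
        state["traces"] = traces
        report["stages"]["simulate"] = "loaded"
        return
    seed = config.seed
    individuals, nest_sites = synthdata.simulate_population(config.population, seed)
    sightings, interactions = synthdata.simulate_social_observations(
        individuals, config.observations, seed + 1
    )
    relatedness = synthdata.simulate_relatedness(individuals, seed + 2)
    # dyad-level similarity effect rides on the tolerance edges
    tol_pairs = [
        tuple(sorted((r.id_i, r.id_j)))
        for r in interactions.itertuples(index=False)
        if r.kind == "tolerance" and r.id_i != r.id_j
    ]
    calls, traces, truth = synthdata.simulate_calls(
        individuals,
        config.calls,
        seed + 3,
        similarity_edges=sorted(set(tol_pairs)),
        similarity_effect=config.similarity_effect,
    )
    state.update(
        individuals=individuals,
        nest_sites=nest_sites,
        sightings=sightings,
        interactions=interactions,
        relatedness=relatedness,
        calls=calls,
        traces=traces,
        truth=truth,
    )
    synthdata.write_tables(
        out / "inputs",
        individuals=individuals,
        nest_sites=nest_sites,
        sightings=sightings,
        interactions=interactions,
        relatedness=relatedness,
        calls=calls,
        traces=traces if config.write_traces else None,
        truth=truth,
    )


def _stage_networks(config, state, out, report):
    individuals = state["individuals"]
    layers = {
        "foraging": networks.foraging_layer(state["sightings"]),
        "mate": networks.binary_layer(state["interactions"], "mate", individuals),
        "affiliative": networks.binary_layer(state["interactions"], "affiliative"),
        "aggression": networks.binary_layer(state["interactions"], "aggression"),
        "nest_distance": networks.nest_distance_layer(individuals, state["nest_sites"]),
    }
    multiplex = networks.MultiplexNetwork(
        (layers["foraging"], layers["mate"], layers["aggression"], layers["affiliative"])
    )
    cent = networks.centralities(layers["foraging"])
    vers = networks.degree_versatility(multiplex).rename_axis("id").reset_index()
    sizes = networks.group_sizes(individuals)
    metrics = individuals[["id", "sex", "age_days"]].merge(cent, on="id", how="left")
    metrics = metrics.merge(vers, on="id", how="left").merge(sizes, on="id", how="left")
    # spatial position proxy: mean normalised nest distance to all others
    nd = layers["nest_distance"]
    mean_nd = {
        i: np.mean([nd.weight(i, j) for j in nd.nodes if j != i]) for i in nd.nodes
    }
    metrics["nest"] = metrics["id"].map(mean_nd)
    # individual-level tolerance: degree in the affiliative layer
    tol_deg = dict(layers["affiliative"].to_networkx(binarize=True).degree())
    metrics["tolerance"] = metrics["id"].map(tol_deg).fillna(0).astype(float)
    state["layers"] = layers
    state["multiplex"] = multiplex
    state["node_metrics"] = metrics
    (out / "networks").mkdir(parents=True, exist_ok=True)
    for name, layer in layers.items():
        networks.write_layer(layer, out / "networks" / f"{name}.tsv")
    _tsv(metrics, out / "networks" / "node_metrics.tsv")


def _stage_distances(config, state, out, report):
    calls, traces = state["calls"], state["traces"]
    between = acoustics.between_individual_distances(
        calls,
        traces,
        call_type="contact",
        max_pairs_per_dyad=config.thresholds.max_pairs_per_dyad,
        seed=config.seed + 10,
    )
    within = acoustics.within_individual_distances(calls, traces, call_type="contact")
    state["between"] = between
    state["within"] = within
    _tsv(between, out / "distances" / "between.tsv")
    _tsv(within, out / "distances" / "within.tsv")
    report["stages"]["distances"] = f"{len(between)} between, {len(within)} within"


def _stage_fit_dyadic(config, state, out, report):
    model = DyadicDistanceModel(state["between"])
    res = model.fit(_sampler_config(config.sampler, config.seed + 20))
    state["dyadic_results"] = res
    _tsv(res.dyad_estimates(), out / "posteriors" / "dyad_similarity.tsv")
    _tsv(res.hyper_estimates(), out / "posteriors" / "dyadic_hyperparameters.tsv")
    report["fits"]["dyadic"] = res.fit_report()


def _stage_fit_diversity(config, state, out, report):
    model = WithinIndividualDistanceModel(state["within"])
    res = model.fit(_sampler_config(config.sampler, config.seed + 21))
    state["diversity_results"] = res
    _tsv(res.individual_estimates(), out / "posteriors" / "individual_diversity.tsv")
    _tsv(res.hyper_estimates(), out / "posteriors" / "within_hyperparameters.tsv")
    report["fits"]["diversity"] = res.fit_report()


def _information_peaks(config, state):
    calls, traces = state["calls"], state["traces"]
    contact = calls[calls["call_type"] == "contact"]
    if "loud" in contact.columns and contact["loud"].notna().any():
        contact = contact[contact["loud"].astype(bool)]
    rows = [
        {
            "individual_id": r.individual_id,
            "call_id": r.call_id,
            "count": acoustics.count_am_peaks(traces[r.call_id], config.thresholds.min_height),
        }
        for r in contact.itertuples(index=False)
    ]
    return pd.DataFrame(rows)


def _predictor_table(state):
    metrics = state["node_metrics"].copy()
    metrics = metrics.rename(columns={"id": "unit_id"})
    metrics["sex"] = (metrics["sex"] == "F").astype(float)
    metrics["age"] = metrics["age_days"].astype(float)
    return metrics


def _stage_fit_information(config, state, out, report):
    peaks = _information_peaks(config, state)
    predictors = _predictor_table(state)
    res = fit_information_model(
        peaks,
        predictors,
        ["degree", "age", "tree_size"],
        _sampler_config(config.sampler, config.seed + 22),
        likelihood=config.information_likelihood,
    )
    state["information_results"] = res
    state["information_peaks"] = peaks
    _tsv(res.slope_estimates(), out / "posteriors" / "information_slopes.tsv")
    report["fits"]["information"] = res.fit_report()


def _stage_fit_repertoire(config, state, out, report):
    table = repertoire.build_repertoire_table(state["calls"], min_calls=config.thresholds.min_calls)
    entropy = table.entropy().rename_axis("unit_id").reset_index()
    _tsv(entropy, out / "repertoire" / "entropy.tsv")
    state["repertoire_table"] = table
    state["entropy"] = entropy
    predictors = _predictor_table(state)
    cov = predictors.set_index("unit_id").loc[
        [i for i in table.model_counts.index if i in set(predictors["unit_id"])],
        ["age", "sex"],
    ].reset_index()
    counts = table.model_counts.loc[cov["unit_id"]]
    dm_cfg = SamplerConfig(
        chains=config.sampler.chains,
        warmup=config.sampler.dm_warmup,
        draws=config.sampler.dm_draws,
        seed=config.seed + 23,
    )
    model = DirichletMultinomialModel(counts, cov)
    res = model.fit(dm_cfg)
    state["composition_results"] = res
    _tsv(res.alpha_estimates(), out / "repertoire" / "alpha.tsv")
    if "sex" in res.covariate_names:
        try:
            _tsv(res.sex_contrast("sex"), out / "repertoire" / "sex_contrast.tsv")
        except ValueError as exc:
            report["fits"]["composition_contrast"] = str(exc)
    report["fits"]["composition"] = res.fit_report()


def _dyadic_predictors(state):
    layers = state["layers"]
    rel = state.get("relatedness")
    dyads = state["between"]["dyad_id"].unique()
    rows = []
    for d in dyads:
        a, b = d.split("|")
        row = {
            "unit_id": d,
            "id_i": a,
            "id_j": b,
            "mate": layers["mate"].weight(a, b),
            "foraging": layers["foraging"].weight(a, b),
            "tolerance": layers["affiliative"].weight(a, b),
            "nest": layers["nest_distance"].weight(a, b, default=np.nan),
        }
        if rel is not None and a in rel.index and b in rel.columns:
            row["relatedness"] = rel.loc[a, b]
        else:
            row["relatedness"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_fit_effects(config, state, out, report):
    sampler = config.sampler
    rows = []
    registry = load_registry()
    for req in config.effects:
        dag_name = registry.loc[registry["outcome"] == req.outcome, "dag"]
        if dag_name.empty:
            raise StageError("fit-effects", f"no registry entry for outcome {req.outcome!r}")
        dag = load_dag(dag_name.iloc[0])
        dag_node = "network_position" if req.exposure in POSITION_METRICS else req.exposure
        spec = build_adjustment(
            EffectSpec(req.outcome, dag_node, req.kind), dag
        )
        # the abstract network_position node maps to a concrete metric
        adjustment = ["degree" if c == "network_position" else c for c in spec.formula[1:]]
        formula = [req.exposure] + [c for c in adjustment if c != req.exposure]
        cfg = _sampler_config(sampler, config.seed + 30 + len(rows))

        if req.outcome == "similarity":
            if "dyadic_results" not in state:
                continue
            outcomes = state["dyadic_results"].dyad_estimates().rename(
                columns={"mean": "est_mean", "sd": "est_sd"}
            )
            predictors = _dyadic_predictors(state)
            res = fit_dyadic_effect_model(outcomes, predictors, formula, cfg)
        elif req.outcome == "diversity":
            if "diversity_results" not in state:
                continue
            outcomes = state["diversity_results"].individual_estimates().rename(
                columns={"mean": "est_mean", "sd": "est_sd"}
            )
            res = fit_individual_effect_model(outcomes, _predictor_table(state), formula, cfg)
        elif req.outcome == "entropy":
            if "entropy" not in state:
                continue
            outcomes = state["entropy"].rename(columns={"entropy": "est_mean"})
            outcomes["est_sd"] = 0.0  # entropy is computed, not estimated
            res = fit_individual_effect_model(
                outcomes, _predictor_table(state), formula, cfg, intercept_prior=(1.0, 1.0)
            )
        elif req.outcome == "information":
            peaks = state.get("information_peaks")
            if peaks is None:
                peaks = _information_peaks(config, state)
            res = fit_information_model(
                peaks, _predictor_table(state), formula, cfg,
                likelihood=config.information_likelihood,
            )
        else:
            raise StageError("fit-effects", f"unknown outcome {req.outcome!r}")
        spec_out = EffectSpec(req.outcome, req.exposure, req.kind, tuple(formula[1:]))
        rows.append(effect_row(spec_out, res))
    table = pd.DataFrame(rows)
    state["effect_table"] = table
    _tsv(table, out / "effects" / "effect_table.tsv")
    report["fits"]["effects"] = f"{len(table)} effect models"


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "networks": _stage_networks,
    "distances": _stage_distances,
    "fit-dyadic": _stage_fit_dyadic,
    "fit-diversity": _stage_fit_diversity,
    "fit-information": _stage_fit_information,
    "fit-repertoire": _stage_fit_repertoire,
    "fit-effects": _stage_fit_effects,
}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(artifact_dir) -> str:
    """Human-readable summary of a completed (or partial) run."""
    art = Path(artifact_dir)
    lines = [f"pipeline artifacts: {art}"]
    rpt = art / "report.json"
    if rpt.exists():
        meta = json.loads(rpt.read_text())
        lines.append(f"seed {meta.get('seed')}  config {meta.get('config_hash')}")
        for fit, info in meta.get("fits", {}).items():
            if isinstance(info, dict) and "worst_hyper_rhat" in info:
                lines.append(f"  {fit}: worst Rhat {info['worst_hyper_rhat']:.3f}")
    else:
        lines.append("(no report.json; incomplete run)")
    eff = art / "effects" / "effect_table.tsv"
    if eff.exists():
        table = pd.read_csv(eff, sep="\t")
        if table.empty:
            lines.append("no effects fitted")
        else:
            lines.append(table.to_string(index=False))
            try:
                from vocsocial.effects import forest_plot

                forest_plot(table, art / "effects" / "forest.png")
                lines.append(f"forest plot: {art / 'effects' / 'forest.png'}")
            except Exception:
                pass
    else:
        lines.append("no effects fitted")
    return "\n".join(lines)
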