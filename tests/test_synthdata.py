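"""Synthetic-data generator: structural constraints, determinism, effects."""

import io

import numpy as np
import pandas as pd
import pytest

from vocsocial.repertoire import CALL_TYPES
from vocsocial.synthdata import (
    CallConfig,
    ConfigError,
    ObservationConfig,
    PopulationConfig,
    simulate_calls,
    simulate_population,
    simulate_relatedness,
    simulate_repertoire_counts,
    simulate_social_observations,
)


def _table_bytes(df):
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


class TestPopulation:
    def test_group_size_caps(self):
        ind, _ = simulate_population(PopulationConfig(n_individuals=100), seed=1)
        chambers = ind.dropna(subset=["entry_id"]).groupby("entry_id").size()
        trees = ind.dropna(subset=["tree_id"]).groupby("tree_id").size()
        assert chambers.between(1, 4).all()
        assert trees.between(1, 20).all()

    def test_degenerate_single_individual(self):
        ind, nests = simulate_population(
            PopulationConfig(n_individuals=1, n_trees=1, unassigned_prob=0.0), seed=0
        )
        assert len(ind) == 1
        assert ind["tree_id"].notna().all()
        assert ind.groupby("tree_id").size().iloc[0] == 1

    def test_deterministic_under_fixed_seed(self):
        a = simulate_population(PopulationConfig(n_individuals=200, n_trees=40), seed=7)
        b = simulate_population(PopulationConfig(n_individuals=200, n_trees=40), seed=7)
        assert _table_bytes(a[0]) == _table_bytes(b[0])
        assert _table_bytes(a[1]) == _table_bytes(b[1])

    def test_infeasible_config_raises(self):
        with pytest.raises(ConfigError):
            simulate_population(
                PopulationConfig(n_individuals=200, n_trees=2, unassigned_prob=0.0), seed=0
            )

    def test_ids_unique_and_entries_share_tree_coords(self):
        ind, nests = simulate_population(PopulationConfig(n_individuals=80), seed=3)
        assert ind["id"].is_unique
        assert nests["entry_id"].is_unique
        for _, grp in nests.groupby("tree_id"):
            assert grp["x"].max() - grp["x"].min() < 5.0  # jitter only


class TestObservations:
    def test_allopreening_concentrates_within_entries(self, small_population):
        individuals, _ = small_population
        cfg = ObservationConfig(n_sessions=80, allopreen_rate=3.0, allopreen_within_entry_prob=0.97)
        _, inter = simulate_social_observations(individuals, cfg, seed=5)
        allo = inter[inter["kind"] == "allopreen"]
        entry = dict(zip(individuals["id"], individuals["entry_id"]))
        within = [
            (not pd.isna(entry[r.id_i]))
            and (not pd.isna(entry[r.id_j]))
            and entry[r.id_i] == entry[r.id_j]
            for r in allo.itertuples(index=False)
        ]
        assert len(allo) > 50
        assert np.mean(within) > 0.9

    def test_zero_rate_gives_empty_kind(self, small_population):
        individuals, _ = small_population
        cfg = ObservationConfig(n_sessions=20, aggression_rate=0.0)
        _, inter = simulate_social_observations(individuals, cfg, seed=5)
        assert (inter["kind"] == "aggression").sum() == 0

    def test_zero_sessions_warns_and_returns_empty(self, small_population):
        individuals, _ = small_population
        with pytest.warns(UserWarning):
            s, i = simulate_social_observations(individuals, ObservationConfig(n_sessions=0), seed=1)
        assert s.empty and i.empty

    def test_sightings_reference_known_individuals_and_determinism(self, small_population):
        individuals, _ = small_population
        cfg = ObservationConfig(n_sessions=15)
        s1, i1 = simulate_social_observations(individuals, cfg, seed=9)
        s2, i2 = simulate_social_observations(individuals, cfg, seed=9)
        assert set(s1["individual"]) <= set(individuals["id"])
        assert _table_bytes(s1) == _table_bytes(s2)
        assert _table_bytes(i1) == _table_bytes(i2)


class TestRelatedness:
    def test_symmetric_with_nan_diagonal(self, small_population):
        individuals, _ = small_population
        rel = simulate_relatedness(individuals, seed=2)
        m = rel.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()

    def test_unrelated_background_is_small(self, small_population):
        individuals, _ = small_population
        rel = simulate_relatedness(individuals, seed=2, kin_pairs=[])
        vals = rel.to_numpy()
        off = vals[~np.isnan(vals)]
        assert 0.0 <= off.min() and off.max() <= 1.0
        assert off.mean() < 0.05

    def test_designated_kin_pairs_near_half(self, small_population):
        individuals, _ = small_population
        ids = list(individuals["id"])
        kin = [(ids[0], ids[1], 0.5), (ids[2], ids[3], 0.5)]
        rel = simulate_relatedness(individuals, seed=4, kin_pairs=kin)
        for a, b, _ in kin:
            assert 0.35 <= rel.loc[a, b] <= 0.65


class TestCalls:
    def test_type_proportions_approach_alpha_without_effects(self, small_population):
        # law of large numbers: beta = 0, very large theta -> proportions -> alpha
        individuals, _ = small_population
        cfg = CallConfig(mean_calls=400, theta=1e6, bump_height_hz=0.0)
        calls, _, _ = simulate_calls(individuals, cfg, seed=11)
        props = calls["call_type"].value_counts(normalize=True)
        for k, t in enumerate(CALL_TYPES):
            assert abs(props.get(t, 0.0) - cfg.alpha[k]) < 0.02

    def test_all_eleven_types_present_at_scale(self, small_population):
        individuals, _ = small_population
        calls, _, _ = simulate_calls(individuals, CallConfig(mean_calls=300), seed=1)
        assert set(calls["call_type"]) == set(CALL_TYPES)

    def test_sex_contrast_on_contact_calls_monte_carlo(self, small_population):
        # configured female deficit on the contact-call log-proportion shows
        # up as a lower female share in nearly every seeded replicate
        individuals, _ = small_population
        beta_sex = tuple([-0.3] + [0.0] * 10)
        hits = 0
        for seed in range(20):
            cfg = CallConfig(mean_calls=80, beta_sex=beta_sex, bump_height_hz=0.0, trace_len=8)
            calls, _, _ = simulate_calls(individuals, cfg, seed=seed)
            df = calls.merge(individuals[["id", "sex"]], left_on="individual_id", right_on="id")
            share = df.groupby("sex")["call_type"].apply(lambda s: (s == "contact").mean())
            if share["F"] < share["M"]:
                hits += 1
        assert hits >= 18  # >= 90% of 20 replicates

    def test_traces_and_truth_deterministic(self, small_population):
        individuals, _ = small_population
        cfg = CallConfig(mean_calls=10, trace_len=40)
        c1, t1, g1 = simulate_calls(individuals, cfg, seed=3)
        c2, t2, g2 = simulate_calls(individuals, cfg, seed=3)
        assert _table_bytes(c1) == _table_bytes(c2)
        assert all(np.array_equal(t1[k], t2[k]) for k in t1)
        assert g1 == g2

    def test_non_simplex_alpha_rejected(self):
        with pytest.raises(Exception):
            CallConfig(alpha=tuple([0.5] * 11))
        rng = np.random.default_rng(0)
        with pytest.raises(ConfigError):
            simulate_repertoire_counts(
                np.full(11, 0.5), np.zeros((1, 11)), np.zeros((2, 1)), [10, 10], 5.0, rng
            )

    def test_within_spread_covariate_increases_embedding_scatter(self, small_population):
        individuals, _ = small_population
        base = CallConfig(mean_calls=30, bump_height_hz=0.0, trace_len=60)
        up = base.model_copy(update={"gamma_within": {"age": 1.0}})
        calls, traces, _ = simulate_calls(individuals, up, seed=6)
        # older birds should have more variable traces (larger within-bird sd)
        merged = calls.merge(individuals[["id", "age_days"]], left_on="individual_id", right_on="id")
        spread = {
            ind: np.mean([np.std(traces[c]) for c in grp["call_id"]])
            for ind, grp in merged.groupby("individual_id")
        }
        var_of_trace = {
            ind: np.std([traces[c].mean() for c in grp["call_id"]])
            for ind, grp in merged.groupby("individual_id")
        }
        ages = individuals.set_index("id")["age_days"]
        common = sorted(var_of_trace)
        r = np.corrcoef(
            np.log(ages.loc[common].to_numpy(float)), [var_of_trace[i] for i in common]
        )[0, 1]
        assert r > 0.2
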