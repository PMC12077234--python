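"""Network layers, SRI, centralities, versatility and group sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import betweenness_oracle, sri_oracle
from vocsocial.networks import (
    MultiplexNetwork,
    NetworkLayer,
    binary_layer,
    centralities,
    degree_versatility,
    foraging_layer,
    group_sizes,
    nest_distance_layer,
    simple_ratio_index,
)


def sightings_frame(rows):
    return pd.DataFrame(rows, columns=["session", "group", "individual"])


class TestSimpleRatioIndex:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 0, 0, 0), 1.0), ((0, 3, 2, 1), 0.0), ((2, 1, 1, 0), 0.5)],
    )
    def test_hand_counts(self, counts, expected):
        assert simple_ratio_index(*counts) == pytest.approx(expected)

    def test_all_zero_is_missing_not_zero(self):
        assert np.isnan(simple_ratio_index(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            simple_ratio_index(-1, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, counts):
        w = simple_ratio_index(*counts)
        assert np.isnan(w) or 0.0 <= w <= 1.0


class TestForagingLayer:
    def test_always_together_gives_edge_one(self):
        rows = [(f"S{k}", f"S{k}G1", i) for k in range(4) for i in ("A", "B")]
        layer = foraging_layer(sightings_frame(rows))
        assert layer.weight("A", "B") == pytest.approx(1.0)

    def test_one_joint_one_alone_each(self):
        rows = [
            ("S1", "S1G1", "A"), ("S1", "S1G1", "B"),
            ("S2", "S2G1", "A"),
            ("S3", "S3G1", "B"),
        ]
        layer = foraging_layer(sightings_frame(rows))
        assert layer.weight("A", "B") == pytest.approx(1 / 3)

    def test_disjoint_sightings_no_edge(self):
        rows = [("S1", "S1G1", "A"), ("S2", "S2G1", "B")]
        layer = foraging_layer(sightings_frame(rows))
        assert ("A", "B") not in layer.edges

    def test_duplicate_individual_deduplicated_with_warning(self):
        rows = [("S1", "S1G1", "A"), ("S1", "S1G1", "A"), ("S1", "S1G1", "B")]
        with pytest.warns(UserWarning):
            layer = foraging_layer(sightings_frame(rows))
        assert layer.weight("A", "B") == pytest.approx(1.0)

    def test_matches_bruteforce_recount_on_random_instances(self):
        rng = np.random.default_rng(0)
        ids = [f"B{k}" for k in range(15)]
        rows = []
        for s in range(20):
            for g in range(3):
                members = rng.choice(ids, size=rng.integers(1, 6), replace=False)
                rows += [(f"S{s}", f"S{s}G{g}", m) for m in members]
        sight = sightings_frame(rows)
        layer = foraging_layer(sight)
        for (a, b), w in layer.edges.items():
            assert w == pytest.approx(sri_oracle(sight, a, b))
        # spot-check some never-together pairs are absent
        for a, b in itertools.combinations(ids, 2):
            if (min(a, b), max(a, b)) not in layer.edges:
                oracle = sri_oracle(sight, a, b)
                assert oracle is None or oracle == 0.0


class TestBinaryLayers:
    def interactions(self, rows):
        return pd.DataFrame(rows, columns=["session", "kind", "id_i", "id_j"])

    def test_shared_entry_gives_mate_edge_without_interactions(self):
        individuals = pd.DataFrame(
            {"id": ["A", "B", "C"], "entry_id": ["E1", "E1", "E2"], "tree_id": ["T1"] * 3}
        )
        layer = binary_layer(self.interactions([]), "mate", individuals)
        assert layer.weight("A", "B") == 1.0
        assert layer.weight("A", "C") == 0.0

    def test_single_fight_gives_undirected_aggression_edge(self):
        layer = binary_layer(self.interactions([("S1", "aggression", "B", "A")]), "aggression")
        assert layer.weight("A", "B") == 1.0 == layer.weight("B", "A")

    def test_affiliative_uses_tolerance_and_allopreen(self):
        rows = [("S1", "tolerance", "A", "B"), ("S1", "allopreen", "C", "D"), ("S1", "aggression", "A", "D")]
        layer = binary_layer(self.interactions(rows), "affiliative")
        assert layer.weight("A", "B") == 1.0 and layer.weight("C", "D") == 1.0
        assert layer.weight("A", "D") == 0.0

    def test_no_events_empty_edges(self):
        assert binary_layer(self.interactions([]), "aggression").edges == {}

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            binary_layer(self.interactions([]), "grooming")


class TestNestDistanceLayer:
    def make(self, entries, assign):
        nest_sites = pd.DataFrame(
            [(t, f"{e}N", e, x, y) for e, (t, x, y) in entries.items()],
            columns=["tree_id", "nest_id", "entry_id", "x", "y"],
        )
        individuals = pd.DataFrame(
            {"id": list(assign), "entry_id": [assign[i] for i in assign],
             "tree_id": [entries[assign[i]][0] if not pd.isna(assign[i]) else pd.NA for i in assign]}
        )
        return individuals, nest_sites

    def test_same_tree_scores_zero_and_max_scores_one(self):
        entries = {"E1": ("T1", 0.0, 0.0), "E2": ("T1", 1.0, 0.5), "E3": ("T2", 30.0, 40.0)}
        ind, nests = self.make(entries, {"A": "E1", "B": "E2", "C": "E3"})
        layer = nest_distance_layer(ind, nests)
        assert layer.weight("A", "B") == 0.0
        assert max(layer.edges.values()) == pytest.approx(1.0)

    def test_pythagorean_normalisation(self):
        entries = {
            "E1": ("T1", 0.0, 0.0), "E2": ("T2", 3.0, 4.0), "E3": ("T3", 0.0, 10.0),
        }
        ind, nests = self.make(entries, {"A": "E1", "B": "E2", "C": "E3"})
        layer = nest_distance_layer(ind, nests)
        assert layer.weight("A", "C") == pytest.approx(1.0)  # max distance 10
        assert layer.weight("A", "B") == pytest.approx(0.5)  # 5 / 10

    def test_unassigned_individuals_excluded(self):
        entries = {"E1": ("T1", 0.0, 0.0), "E2": ("T2", 3.0, 4.0)}
        ind, nests = self.make(entries, {"A": "E1", "B": "E2", "C": pd.NA})
        layer = nest_distance_layer(ind, nests)
        assert "C" not in layer.nodes


class TestCentralities:
    def as_layer(self, edges, nodes=None):
        nodes = nodes or sorted({n for e in edges for n in e})
        return NetworkLayer("foraging", tuple(nodes), {e: 1.0 for e in edges})

    def test_path_graph_betweenness(self):
        cent = centralities(self.as_layer([("A", "B"), ("B", "C")])).set_index("id")
        assert cent.loc["B", "betweenness"] == pytest.approx(1.0)
        assert cent.loc["A", "betweenness"] == 0.0

    def test_star_center_betweenness(self):
        edges = [("hub", f"L{k}") for k in range(5)]
        cent = centralities(self.as_layer(edges)).set_index("id")
        assert cent.loc["hub", "betweenness"] == pytest.approx(10.0)  # C(5,2)

    def test_complete_graph_symmetry(self):
        edges = list(itertools.combinations("ABCD", 2))
        cent = centralities(self.as_layer(edges))
        assert (cent["betweenness"] == 0).all()
        assert np.allclose(cent["eigenvector"], 1.0)

    def test_betweenness_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for trial in range(12):
            n = int(rng.integers(4, 9))
            nodes = [f"N{k}" for k in range(n)]
            edges = [e for e in itertools.combinations(nodes, 2) if rng.uniform() < 0.45]
            cent = centralities(self.as_layer(edges, nodes)).set_index("id")
            oracle = betweenness_oracle(edges, nodes)
            present = set(cent.index)
            for v in present:
                assert cent.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-9)

    def test_eigenvector_max_normalised(self):
        edges = [("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")]
        cent = centralities(self.as_layer(edges))
        assert cent["eigenvector"].max() == pytest.approx(1.0)
        assert (cent["eigenvector"] >= 0).all()


class TestVersatility:
    def test_single_layer_equals_degree(self):
        layer = NetworkLayer("mate", ("A", "B", "C"), {("A", "B"): 1.0})
        v = degree_versatility(MultiplexNetwork((layer,)))
        assert v["A"] == 1 and v["C"] == 0

    def test_matches_summed_per_layer_degrees_on_random_multiplexes(self):
        rng = np.random.default_rng(9)
        names = ["foraging", "mate", "aggression", "affiliative"]
        for trial in range(100):
            nodes = [f"B{k}" for k in range(int(rng.integers(3, 10)))]
            layers = []
            for name in names:
                edges = {
                    e: 1.0 for e in itertools.combinations(nodes, 2) if rng.uniform() < 0.3
                }
                sub = tuple(rng.choice(nodes, size=max(2, int(rng.integers(2, len(nodes) + 1))), replace=False))
                edges = {e: w for e, w in edges.items() if e[0] in sub and e[1] in sub}
                layers.append(NetworkLayer(name, sub, edges))
            mux = MultiplexNetwork(tuple(layers))
            v = degree_versatility(mux)
            for node in mux.nodes:
                expected = 0
                for la in layers:
                    expected += sum(1 for (i, j) in la.edges if node in (i, j))
                assert v[node] == expected

    def test_nest_layer_rejected_from_multiplex(self):
        nest = NetworkLayer("nest_distance", ("A", "B"), {("A", "B"): 0.4})
        with pytest.raises(ValueError):
            MultiplexNetwork((nest,))


class TestGroupSizes:
    def test_sole_occupant(self):
        ind = pd.DataFrame({"id": ["A"], "entry_id": ["E1"], "tree_id": ["T1"]})
        gs = group_sizes(ind).set_index("id")
        assert gs.loc["A", "chamber_size"] == 1 and gs.loc["A", "tree_size"] == 1

    def test_hand_counted_sizes(self):
        # tree T1 holds one entry of 4 and one of 2 -> tree size 6
        ind = pd.DataFrame(
            {
                "id": list("ABCDEF"),
                "entry_id": ["E1"] * 4 + ["E2"] * 2,
                "tree_id": ["T1"] * 6,
            }
        )
        gs = group_sizes(ind).set_index("id")
        assert gs.loc["A", "chamber_size"] == 4
        assert gs.loc["E", "chamber_size"] == 2
        assert (gs["tree_size"] == 6).all()

    def test_missing_assignment_gives_missing_not_zero(self):
        ind = pd.DataFrame({"id": ["A", "B"], "entry_id": ["E1", pd.NA], "tree_id": ["T1", pd.NA]})
        gs = group_sizes(ind).set_index("id")
        assert np.isnan(gs.loc["B", "chamber_size"])

    def test_caps_hold_on_generator_defaults(self, small_population):
        individuals, _ = small_population
        gs = group_sizes(individuals)
        assert gs["chamber_size"].dropna().between(1, 4).all()
        assert gs["tree_size"].dropna().between(1, 20).all()


def test_layer_symmetry_and_self_edge_rejection():
    layer = NetworkLayer("mate", ("A", "B"), {("B", "A"): 1.0})
    assert layer.weight("A", "B") == layer.weight("B", "A") == 1.0
    with pytest.raises(ValueError):
        NetworkLayer("mate", ("A",), {("A", "A"): 1.0})
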