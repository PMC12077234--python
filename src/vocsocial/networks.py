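"""Construction of the five social-network layers and node-level metrics.

Layers
------
foraging
    Gambit-of-the-group association network: two individuals are connected
    if ever observed foraging in the same group, weighted by the simple
    ratio index (fraction of sampling sessions in which they were together,
    out of sessions in which at least one was seen).
mate
    Binary: individuals assigned to the same nest entry (chamber), or
    observed allopreening / recorded as mates.
affiliative
    Binary: at least one close-tolerance or allopreening observation.
aggression
    Binary, undirected: at least one displacement or fight.
nest_distance
    Planar Euclidean distance between assigned nest entries, normalised by
    the maximum observed distance (same tree scored exactly 0).

The multiplex network bundles the four interaction layers (the nest layer
is excluded) and supports *degree versatility*: the per-individual sum of
unweighted degree across layers.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINARY_KINDS = ("mate", "aggression", "affiliative")
LAYER_NAMES = ("foraging", "mate", "affiliative", "aggression", "nest_distance")

__all__ = [
    "NetworkLayer",
    "MultiplexNetwork",
    "simple_ratio_index",
    "foraging_layer",
    "binary_layer",
    "nest_distance_layer",
    "centralities",
    "degree_versatility",
    "group_sizes",
    "write_layer",
    "read_layer",
]


def _key(i, j):
    return (i, j) if i <= j else (j, i)


@dataclass
class NetworkLayer:
    """A symmetric weighted graph over the individual universe.

    Edges are stored once per unordered pair under a canonical sorted key;
    :meth:`weight` resolves either orientation. Self-edges are forbidden.
    """

    name: str
    nodes: tuple
    edges: dict = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for (i, j), w in self.edges.items():
            if i == j:
                raise ValueError(f"self-edge on node {i!r}")
            clean[_key(i, j)] = float(w)
        self.edges = clean
        self.nodes = tuple(sorted(set(self.nodes)))

    def weight(self, i, j, default=0.0):
        return self.edges.get(_key(i, j), default)

    def to_networkx(self, binarize=False):
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), w in self.edges.items():
            if w > 0:
                g.add_edge(i, j, weight=1.0 if binarize else w)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, j, w) for (i, j), w in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["id_i", "id_j", "weight"])


@dataclass
class MultiplexNetwork:
    """Four interaction layers over the union of their node sets.

    The nest-distance layer is deliberately excluded (it duplicates the
    mate layer's information).
    """

    layers: tuple

    def __post_init__(self):
        names = [la.name for la in self.layers]
        if "nest_distance" in names:
            raise ValueError("the nest-distance layer is not part of the multiplex")
        self.layers = tuple(self.layers)

    @property
    def nodes(self):
        universe = set()
        for la in self.layers:
            universe.update(la.nodes)
        return tuple(sorted(universe))


def simple_ratio_index(n_together, n_only_a, n_only_b, n_both_seen_apart):
    """Simple ratio index x / (x + yA + yB + yAB) in [0, 1].

    Returns NaN when all counts are zero (the dyad was never sampled);
    never coerces an unsampled dyad to 0.
    """
    counts = (n_together, n_only_a, n_only_b, n_both_seen_apart)
    if any(c < 0 for c in counts):
        raise ValueError("sighting counts must be nonnegative")
    denom = sum(counts)
    if denom == 0:
        return float("nan")
    return n_together / denom


def foraging_layer(sightings: pd.DataFrame) -> NetworkLayer:
    """Gambit-of-the-group foraging network with SRI edge weights.

    `sightings` columns: ``session``, ``group``, ``individual``. Within a
    session each pair is counted together at most once (session-level
    dedup); an individual listed twice in one group is deduplicated with a
    warning. Pairs never co-sighted share no edge.
    """
    required = {"session", "group", "individual"}
    if not required.issubset(sightings.columns):
        raise ValueError(f"sightings must have columns {sorted(required)}")
    n_dupes = 0
    session_seen: dict = defaultdict(set)
    together = Counter()
    per_session_groups: dict = defaultdict(lambda: defaultdict(set))
    for row in sightings.itertuples(index=False):
        grp = per_session_groups[row.session][row.group]
        if row.individual in grp:
            n_dupes += 1
        grp.add(row.individual)
        session_seen[row.session].add(row.individual)
    if n_dupes:
        warnings.warn(f"deduplicated {n_dupes} repeated individual entries within groups")

    for session, groups in per_session_groups.items():
        pairs = set()
        for members in groups.values():
            for i, j in itertools.combinations(sorted(members), 2):
                pairs.add((i, j))
        together.update(pairs)

    seen_sessions = defaultdict(set)
    for session, members in session_seen.items():
        for i in members:
            seen_sessions[i].add(session)

    edges = {}
    for (i, j), x in together.items():
        si, sj = seen_sessions[i], seen_sessions[j]
        n_both = len(si & sj)
        denom = len(si) + len(sj) - n_both  # x + yA + yB + yAB
        w = x / denom
        if w > 0:
            edges[(i, j)] = w
    nodes = tuple(seen_sessions)
    return NetworkLayer("foraging", nodes, edges)


def binary_layer(interactions: pd.DataFrame, kind: str, individuals: pd.DataFrame | None = None) -> NetworkLayer:
    """Build one of the binary layers from typed dyadic events.

    `interactions` columns: ``kind`` in {mate, allopreen, tolerance,
    aggression}, ``id_i``, ``id_j``. The mate layer additionally connects
    all individuals sharing a nest entry (requires `individuals` with an
    ``entry_id`` column); allopreening pairs are folded into it. The
    affiliative layer uses close tolerance and allopreening; the aggression
    layer any aggressive event, direction ignored.
    """
    if kind not in BINARY_KINDS:
        raise ValueError(f"unknown layer kind {kind!r}; expected one of {BINARY_KINDS}")
    if kind == "mate":
        event_kinds = {"mate", "allopreen"}
    elif kind == "affiliative":
        event_kinds = {"tolerance", "allopreen"}
    else:
        event_kinds = {"aggression"}

    edges = {}
    nodes = set()
    if len(interactions):
        sub = interactions[interactions["kind"].isin(event_kinds)]
        for row in sub.itertuples(index=False):
            if row.id_i == row.id_j:
                continue
            edges[_key(row.id_i, row.id_j)] = 1.0
        nodes.update(interactions["id_i"])
        nodes.update(interactions["id_j"])

    if kind == "mate" and individuals is not None:
        assigned = individuals.dropna(subset=["entry_id"])
        for _, grp in assigned.groupby("entry_id"):
            ids = sorted(grp["id"])
            for i, j in itertools.combinations(ids, 2):
                edges[(i, j)] = 1.0
            nodes.update(ids)
    return NetworkLayer(kind, tuple(nodes), edges)


def nest_distance_layer(individuals: pd.DataFrame, nest_sites: pd.DataFrame) -> NetworkLayer:
    """Normalised nest-to-nest distance for all assigned individuals.

    Distances are planar Euclidean between the entries individuals are
    assigned to, divided by the maximum observed distance so the layer
    spans [0, 1]; two entries in the same tree score exactly 0.
    Unassigned individuals are excluded (logged).
    """
    entry_xy = nest_sites.set_index("entry_id")[["x", "y", "tree_id"]]
    assigned = individuals.dropna(subset=["entry_id"])
    dropped = set(individuals["id"]) - set(assigned["id"])
    if dropped:
        logger.info("nest_distance_layer: excluding %d unassigned individuals", len(dropped))
    ids = list(assigned["id"])
    entries = list(assigned["entry_id"])
    missing = sorted(set(entries) - set(entry_xy.index))
    if missing:
        raise ValueError(f"entry ids without nest-site coordinates: {missing}")
    xy = entry_xy.loc[entries, ["x", "y"]].to_numpy(float)
    trees = entry_xy.loc[entries, "tree_id"].to_numpy()

    raw = {}
    for a, b in itertools.combinations(range(len(ids)), 2):
        if trees[a] == trees[b]:
            d = 0.0
        else:
            d = float(np.hypot(*(xy[a] - xy[b])))
        raw[_key(ids[a], ids[b])] = d
    dmax = max(raw.values(), default=0.0)
    if dmax > 0:
        raw = {k: v / dmax for k, v in raw.items()}
    return NetworkLayer("nest_distance", tuple(ids), raw)


def centralities(layer: NetworkLayer) -> pd.DataFrame:
    """Unweighted degree, betweenness and eigenvector centrality per node.

    All three metrics are computed on the binarised graph (edge present iff
    weight > 0). Betweenness is the unnormalised shortest-path count
    (fractional credit when shortest paths tie); eigenvector centrality is
    computed per connected component and scaled so the component maximum is
    1 (isolated nodes score 0).
    """
    g = layer.to_networkx(binarize=True)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["id", "degree", "betweenness", "eigenvector"])
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    eig = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            eig[next(iter(comp))] = 0.0
            continue
        if len(comp) == 2:  # symmetric pair; eigensolver needs n > 2
            for n in comp:
                eig[n] = 1.0
            continue
        sub = g.subgraph(comp)
        scores = nx.eigenvector_centrality_numpy(sub)
        top = max(scores.values())
        for n, s in scores.items():
            eig[n] = abs(s) / abs(top)
    out = pd.DataFrame(
        {
            "id": sorted(g.nodes()),
        }
    )
    out["degree"] = out["id"].map(deg)
    out["betweenness"] = out["id"].map(btw)
    out["eigenvector"] = out["id"].map(eig)
    return out


def degree_versatility(multiplex: MultiplexNetwork) -> pd.Series:
    """Unweighted degree summed across the multiplex layers.

    A node absent from a layer contributes 0 there; isolated-everywhere
    nodes score 0.
    """
    total = Counter({n: 0 for n in multiplex.nodes})
    for la in multiplex.layers:
        g = la.to_networkx(binarize=True)
        for n, d in g.degree():
            total[n] += d
    return pd.Series(dict(total), name="versatility").sort_index()


def group_sizes(individuals: pd.DataFrame) -> pd.DataFrame:
    """Chamber (nest-entry) and tree group size per individual.

    Counts include the focal individual. Individuals without an assignment
    get a missing value, never 0.
    """
    out = individuals[["id"]].copy()
    chamber = individuals.groupby("entry_id")["id"].transform("count")
    tree = individuals.groupby("tree_id")["id"].transform("count")
    out["chamber_size"] = chamber.where(individuals["entry_id"].notna())
    out["tree_size"] = tree.where(individuals["tree_id"].notna())
    return out


def write_layer(layer: NetworkLayer, path):
    layer.to_frame().to_csv(path, sep="\t", index=False)


def read_layer(path, name) -> NetworkLayer:
    df = pd.read_csv(path, sep="\t")
    edges = {(r.id_i, r.id_j): r.weight for r in df.itertuples(index=False)}
    nodes = set(df["id_i"]) | set(df["id_j"])
    return NetworkLayer(name, tuple(nodes), edges)
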