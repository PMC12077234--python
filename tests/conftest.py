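"""Shared fixtures and independent oracles used across the test suite."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vocsocial.synthdata import PopulationConfig, simulate_population


def entropy_oracle(counts):
    """Brute-force Shannon entropy by direct summation (natural log)."""
    total = float(sum(counts))
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def sri_oracle(sightings: pd.DataFrame, a, b):
    """Recount the simple ratio index for one pair from raw sightings."""
    x = y_ab = y_a = y_b = 0
    for _, sess in sightings.groupby("session"):
        groups = [set(g["individual"]) for _, g in sess.groupby("group")]
        seen_a = any(a in g for g in groups)
        seen_b = any(b in g for g in groups)
        together = any(a in g and b in g for g in groups)
        if together:
            x += 1
        elif seen_a and seen_b:
            y_ab += 1
        elif seen_a:
            y_a += 1
        elif seen_b:
            y_b += 1
    denom = x + y_a + y_b + y_ab
    return None if denom == 0 else x / denom


def betweenness_oracle(edges, nodes):
    """Exhaustive shortest-path betweenness (fractional credit on ties)."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    def all_paths(s, t):
        # enumerate all simple paths, keep the shortest ones
        paths, best = [], None
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                if best is None or len(path) < best:
                    best, paths = len(path), [path]
                elif len(path) == best:
                    paths.append(path)
                continue
            if best is not None and len(path) >= best:
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))
        return paths

    btw = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


def dtw_oracle(a, b, center=True):
    """Exhaustive minimisation over all monotone warping paths (len <= ~7)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if center:
        a = a - a.mean()
        b = b - b.mean()
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0] / (n + m)


@pytest.fixture(scope="session")
def small_population():
    return simulate_population(PopulationConfig(n_individuals=60, n_trees=15), seed=42)
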