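"""Acoustic distance and information-content measures on F0 traces.

Calls are represented by their smoothed fundamental-frequency (F0) traces,
sampled at a uniform step. Pairwise acoustic distance is dynamic time
warping (DTW) with absolute-difference local cost, a symmetric step
pattern, and normalisation by the summed trace lengths; traces are
mean-centred first so that the distance reflects contour shape rather than
register. Information content of a call is the number of prominent
amplitude-modulation peaks in its trace (prominence threshold
``min_height``, default 30, matching the upstream tooling convention).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


def _dtw_total_cost(a, b):  # pragma: no cover - replaced by jit when available
    n, m = a.size, b.size
    acc = np.empty((n, m))
    acc[0, 0] = abs(a[0] - b[0])
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            if acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            acc[i, j] = best + abs(a[i] - b[j])
    return acc[n - 1, m - 1]


try:  # optional JIT; pure-python fallback is exact but slower
    from numba import njit

    _dtw_total_cost = njit(cache=False)(_dtw_total_cost)
except ImportError:  # pragma: no cover
    pass

__all__ = [
    "dtw_distance",
    "between_individual_distances",
    "within_individual_distances",
    "count_am_peaks",
    "dyad_id",
]

#: default prominence threshold for amplitude-modulation peak counting
MIN_HEIGHT = 30.0


def dtw_distance(trace_a, trace_b, center=True):
    """Path-length-normalised DTW distance between two F0 traces.

    The optimal monotone alignment minimises the cumulative absolute F0
    difference with steps (i-1,j), (i,j-1), (i-1,j-1); the minimal
    cumulative cost is divided by ``len(a) + len(b)``. With ``center=True``
    (default) each trace is mean-centred first, so the distance is
    invariant to a constant pitch offset.

    Raises
    ------
    ValueError
        If either trace has fewer than 2 samples.
    """
    a = np.asarray(trace_a, dtype=float).ravel()
    b = np.asarray(trace_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("DTW requires traces with at least 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in F0 trace")
    if center:
        a = a - a.mean()
        b = b - b.mean()
    return float(_dtw_total_cost(a, b) / (a.size + b.size))


def dyad_id(ind_a, ind_b):
    """Order-invariant identifier for an unordered pair of individuals."""
    a, b = sorted((str(ind_a), str(ind_b)))
    return f"{a}|{b}"


def _subset(calls: pd.DataFrame, call_type):
    if call_type is not None:
        calls = calls[calls["call_type"] == call_type]
    return calls.reset_index(drop=True)


def between_individual_distances(
    calls: pd.DataFrame,
    traces: dict,
    call_type: str | None = "contact",
    max_pairs_per_dyad: int | None = None,
    seed: int = 0,
    center: bool = True,
) -> pd.DataFrame:
    """All cross-individual call-pair distances for one call type.

    Parameters
    ----------
    calls : DataFrame
        Columns ``call_id``, ``individual_id``, ``recording_id``,
        ``call_type``.
    traces : dict
        Maps call_id to a 1-D F0 array.
    max_pairs_per_dyad : int, optional
        Random per-dyad cap on the O(n^2) pair explosion; default keeps
        every pair.

    Returns
    -------
    DataFrame
        One row per unordered cross-individual call pair: ``call_i``,
        ``call_j``, ``distance``, ``dyad_id``, ``ind_i``, ``ind_j``,
        ``rec_i``, ``rec_j``.
    """
    sub = _subset(calls, call_type)
    groups = {
        ind: list(zip(g["call_id"], g["recording_id"]))
        for ind, g in sub.groupby("individual_id")
    }
    rng = np.random.default_rng(seed)
    rows = []
    for ind_a, ind_b in itertools.combinations(sorted(groups), 2):
        pairs = list(itertools.product(groups[ind_a], groups[ind_b]))
        if max_pairs_per_dyad is not None and len(pairs) > max_pairs_per_dyad:
            idx = rng.choice(len(pairs), size=max_pairs_per_dyad, replace=False)
            pairs = [pairs[k] for k in sorted(idx)]
        for (ci, ri), (cj, rj) in pairs:
            rows.append(
                {
                    "call_i": ci,
                    "call_j": cj,
                    "distance": dtw_distance(traces[ci], traces[cj], center=center),
                    "dyad_id": dyad_id(ind_a, ind_b),
                    "ind_i": ind_a,
                    "ind_j": ind_b,
                    "rec_i": ri,
                    "rec_j": rj,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["call_i", "call_j", "distance", "dyad_id", "ind_i", "ind_j", "rec_i", "rec_j"],
    )


def within_individual_distances(
    calls: pd.DataFrame,
    traces: dict,
    call_type: str | None = "contact",
    center: bool = True,
) -> pd.DataFrame:
    """All within-individual call-pair distances for one call type.

    Individuals with a single call of the type contribute nothing. Pairs of
    calls from the same recording carry ``same_recording=True`` so the
    diversity model can control for recording effects.
    """
    sub = _subset(calls, call_type)
    rows = []
    for ind, g in sub.groupby("individual_id"):
        items = list(zip(g["call_id"], g["recording_id"]))
        for (ci, ri), (cj, rj) in itertools.combinations(items, 2):
            rows.append(
                {
                    "call_i": ci,
                    "call_j": cj,
                    "distance": dtw_distance(traces[ci], traces[cj], center=center),
                    "individual_id": ind,
                    "rec_i": ri,
                    "rec_j": rj,
                    "same_recording": ri == rj,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["call_i", "call_j", "distance", "individual_id", "rec_i", "rec_j", "same_recording"],
    )


def count_am_peaks(trace, min_height: float = MIN_HEIGHT) -> int:
    """Number of amplitude-modulation peaks in a smoothed trace.

    A peak is a local maximum whose prominence (height above the higher of
    the two flanking troughs) is at least ``min_height``; trace endpoints
    are never peaks. Invariant to adding a constant offset.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot count peaks of an empty trace")
    peaks, _ = find_peaks(x, prominence=min_height)
    return int(peaks.size)
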