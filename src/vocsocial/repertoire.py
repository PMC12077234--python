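"""Vocal repertoire diversity: per-individual call-type counts and entropy.

The repertoire of an individual is summarised by its counts over the 11
described call types. Repertoire diversity is the Shannon entropy
``-sum(p_i * log(p_i))`` of the type proportions (natural log by default;
higher = more even use of more types). Individuals with fewer than 30
recorded vocalizations are excluded from model datasets to avoid
small-sample outliers, and the two rarest types (*frill* and *other
tonal*) are dropped before fitting the composition model, leaving 9
modelled types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical call-type labels (the first, the contact call, dominates usage)
CALL_TYPES = (
    "contact",
    "alarm",
    "growl",
    "shriek",
    "kazoo",
    "chatter",
    "trill",
    "whistle",
    "warble",
    "frill",
    "other_tonal",
)

#: types too rare to model in the composition analysis
DROP_TYPES = ("frill", "other_tonal")

#: minimum vocalizations for an individual to enter repertoire analyses
MIN_CALLS = 30

__all__ = ["CALL_TYPES", "DROP_TYPES", "MIN_CALLS", "repertoire_entropy", "build_repertoire_table", "RepertoireTable"]


def repertoire_entropy(counts, base: float | None = None) -> float:
    """Shannon entropy of a repertoire's call-type proportions.

    Zero-count types contribute 0 (the ``p log p -> 0`` limit). Natural
    log by default; pass ``base`` for other units.

    Raises
    ------
    ValueError
        If all counts are zero or any count is negative.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("negative call-type count")
    total = c.sum()
    if total == 0:
        raise ValueError("entropy undefined for an empty repertoire")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class RepertoireTable:
    """Per-individual call-type counts, full and composition-model views.

    Attributes
    ----------
    counts : DataFrame
        Individuals x all call types (used for entropy).
    model_counts : DataFrame
        Individuals x retained types (rare types dropped) for the
        Dirichlet-multinomial composition model.
    excluded : list
        Individuals dropped for having fewer than the minimum number of
        vocalizations.
    """

    counts: pd.DataFrame
    model_counts: pd.DataFrame
    excluded: list

    def entropy(self, base: float | None = None) -> pd.Series:
        return self.counts.apply(lambda row: repertoire_entropy(row.to_numpy(), base=base), axis=1).rename("entropy")


def build_repertoire_table(
    calls: pd.DataFrame,
    min_calls: int = MIN_CALLS,
    drop_types=DROP_TYPES,
    call_types=CALL_TYPES,
) -> RepertoireTable:
    """Tabulate per-individual call-type counts and apply inclusion rules.

    Parameters
    ----------
    calls : DataFrame
        Columns ``individual_id`` and ``call_type``.
    min_calls : int
        Individuals with fewer total vocalizations are excluded (with a
        report in ``excluded``).
    drop_types : sequence
        Types removed from the composition-model view only; entropy still
        uses all types.

    Raises
    ------
    ValueError
        On call-type labels outside `call_types` (all offenders listed).
    """
    if calls.empty:
        warnings.warn("no call records supplied; repertoire table is empty")
        empty = pd.DataFrame(columns=list(call_types))
        kept = [t for t in call_types if t not in set(drop_types)]
        return RepertoireTable(empty, pd.DataFrame(columns=kept), [])
    unknown = sorted(set(calls["call_type"]) - set(call_types))
    if unknown:
        raise ValueError(f"unknown call-type labels: {unknown}")
    table = (
        calls.groupby(["individual_id", "call_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(call_types), fill_value=0)
    )
    totals = table.sum(axis=1)
    excluded = sorted(totals.index[totals < min_calls])
    table = table.loc[totals >= min_calls]
    kept = [t for t in call_types if t not in set(drop_types)]
    return RepertoireTable(table, table[kept].copy(), excluded)
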