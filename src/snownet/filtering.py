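"""Occurrence-based ASV filtering and the fungal × bacterial threshold grid.

Filtering is by occurrence (number of samples an ASV is detected in, count
≥ 1), never by read abundance.  Each kingdom gets its own vector of
occurrence thresholds; the Cartesian product of the two vectors defines a
grid of filtered table pairs, from which one network per condition is later
inferred.  Default thresholds are the study's: 5, 7, 9, 11, 19 samples for
fungi and 10, 20, 31, 39, 46 for bacteria (5 × 5 = 25 pairs).

Occurrence is computed on the full (both-condition) dataset before any
condition split: the table is filtered once and each condition's network is
inferred from the same filtered ASV panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .tables import AsvTable

logger = logging.getLogger(__name__)

DEFAULT_FUNGAL_THRESHOLDS: tuple[int, ...] = (5, 7, 9, 11, 19)
DEFAULT_BACTERIAL_THRESHOLDS: tuple[int, ...] = (10, 20, 31, 39, 46)


class FilterPair(NamedTuple):
    """One cell of the threshold grid: (fungal threshold, bacterial threshold)."""

    t_f: int
    t_b: int


@dataclass
class FilteredPairTable:
    """Paired fungal/bacterial tables filtered at one threshold pair."""

    fungal: AsvTable
    bacterial: AsvTable
    pair: FilterPair


def occurrence(table: AsvTable) -> pd.Series:
    """Number of samples each ASV is detected in (count ≥ 1)."""
    return (table.counts > 0).sum(axis=0)


def filter_by_occurrence(table: AsvTable, threshold: int) -> AsvTable:
    """Keep exactly the ASVs detected in at least ``threshold`` samples.

    Samples are kept unchanged; a sample left without any reads is allowed
    (downstream steps warn about it).
    """
    if threshold < 1:
        raise ValueError(f"threshold must be ≥ 1, got {threshold}")
    occ = occurrence(table)
    keep = occ.index[occ >= threshold]
    if len(keep) == 0:
        raise ValueError(
            f"no {table.kingdom} ASVs survive occurrence threshold {threshold}"
        )
    filtered = AsvTable(table.counts[list(keep)].copy(), table.kingdom)
    empty = filtered.depths() == 0
    if empty.any():
        logger.warning(
            "%d sample(s) have zero reads after filtering %s at threshold %d",
            int(empty.sum()), table.kingdom, threshold,
        )
    return filtered


def build_grid(
    fungal: AsvTable,
    bacterial: AsvTable,
    t_f_list: Sequence[int] = DEFAULT_FUNGAL_THRESHOLDS,
    t_b_list: Sequence[int] = DEFAULT_BACTERIAL_THRESHOLDS,
) -> list[FilteredPairTable]:
    """All |t_f_list| × |t_b_list| filtered table pairs, fungal-threshold major."""
    if not t_f_list or not t_b_list:
        raise ValueError("threshold lists must be non-empty")
    fungal_filtered = {}
    bacterial_filtered = {}
    out = []
    for t_f in sorted(t_f_list):
        for t_b in sorted(t_b_list):
            pair = FilterPair(t_f=t_f, t_b=t_b)
            try:
                if t_f not in fungal_filtered:
                    fungal_filtered[t_f] = filter_by_occurrence(fungal, t_f)
                if t_b not in bacterial_filtered:
                    bacterial_filtered[t_b] = filter_by_occurrence(bacterial, t_b)
            except ValueError as exc:
                raise ValueError(f"filter pair {pair}: {exc}") from exc
            out.append(
                FilteredPairTable(
                    fungal=fungal_filtered[t_f], bacterial=bacterial_filtered[t_b], pair=pair
                )
            )
    return out


def suggest_thresholds(occurrences: pd.Series | np.ndarray, k: int = 5) -> list[int]:
    """Candidate occurrence thresholds at the ``k`` sharpest shoulders of the
    retention curve.

    The retention curve r(t) counts ASVs detected in ≥ t samples.  Candidates
    sit where the relative drop (r(t) − r(t+1)) / r(t) is largest — i.e. where
    raising the threshold by one would discard the most ASVs — with ties
    broken toward smaller thresholds.  The suggestion is advisory; grid
    thresholds are explicit configuration.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    occ = np.asarray(occurrences, dtype=int)
    if occ.size == 0:
        raise ValueError("empty occurrence distribution")
    t_max = int(occ.max())
    ts = np.arange(1, t_max + 1)
    retained = np.array([(occ >= t).sum() for t in ts], dtype=float)
    drops = np.zeros(t_max)
    drops[:-1] = (retained[:-1] - retained[1:]) / np.maximum(retained[:-1], 1.0)
    drops[-1] = retained[-1] / max(retained[-1], 1.0)  # everything gone past t_max

    distinct = np.unique(occ)
    if len(distinct) == 1:
        logger.warning("flat occurrence distribution; returning evenly spaced thresholds")
        return [int(t) for t in np.unique(np.linspace(1, max(t_max, 1), k).round())]
    if k >= len(distinct):
        if k > len(distinct):
            logger.warning(
                "requested %d thresholds but only %d distinct occurrence values", k, len(distinct)
            )
        return [int(v) for v in distinct]
    # stable sort on -drop keeps smaller thresholds first among ties
    order = np.argsort(-drops, kind="stable")
    return sorted(int(ts[i]) for i in order[:k])
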