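"""Consensus of associations across the filter grid.

A single network depends on an arbitrary filtering choice; associations that
re-appear across many of a condition's networks ("frequent associations",
by default in more than five of the 25 networks) are the robust signal.
Frequent fungal–bacterial associations are further classified by condition
specificity (snow-free-only / snow-covered-only / both), summarized at genus
level, and — on synthetic data — scored against the planted ground truth.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import AssociationNetwork
from .synthetic import SyntheticTruth, truth_edge_set
from .tables import BACTERIA, CONDITIONS, FUNGI, SNOW_COVERED, SNOW_FREE, Taxonomy

logger = logging.getLogger(__name__)

DEFAULT_MIN_NETWORKS = 6  # "more than five networks"


def _consensus(signs: list[int]) -> str:
    pos = sum(1 for s in signs if s > 0)
    neg = len(signs) - pos
    if pos > neg:
        return "+"
    if neg > pos:
        return "-"
    return "mixed"


@dataclass
class AssociationRecord:
    """One association's footprint across the network ensemble."""

    pair: tuple[str, str]  # sorted ASV ids
    kingdoms: tuple[str, str]  # aligned with `pair`
    n_snow_free: int
    n_snow_covered: int
    signs_snow_free: list[int] = field(default_factory=list)
    signs_snow_covered: list[int] = field(default_factory=list)

    @property
    def all_signs(self) -> list[int]:
        return self.signs_snow_free + self.signs_snow_covered

    @property
    def consensus_sign(self) -> str:
        return _consensus(self.all_signs)

    @property
    def fraction_positive(self) -> float:
        signs = self.all_signs
        return sum(1 for s in signs if s > 0) / len(signs) if signs else float("nan")

    @property
    def is_fb(self) -> bool:
        return set(self.kingdoms) == {FUNGI, BACTERIA}

    def count_for(self, condition: str) -> int:
        return self.n_snow_free if condition == SNOW_FREE else self.n_snow_covered

    def frequent_in(self, condition: str, min_networks: int) -> bool:
        return self.count_for(condition) >= min_networks


def tally_associations(
    networks: list[AssociationNetwork],
) -> dict[frozenset[str], AssociationRecord]:
    """Count, per condition, how many networks contain each association.

    Every association is counted once per network, regardless of weight.
    """
    counts: dict[frozenset[str], dict[str, list[int]]] = defaultdict(
        lambda: {SNOW_FREE: [], SNOW_COVERED: []}
    )
    kingdoms: dict[str, str] = {}
    for net in networks:
        if net.condition not in CONDITIONS:
            raise ValueError(f"network {net.label()} has no condition tag")
        for a, b in net.graph.edges:
            counts[frozenset((a, b))][net.condition].append(net.edge_sign(a, b))
            kingdoms[a] = net.kingdom_of(a)
            kingdoms[b] = net.kingdom_of(b)
    records = {}
    for pair_key, by_cond in counts.items():
        pair = tuple(sorted(pair_key))
        records[pair_key] = AssociationRecord(
            pair=pair,
            kingdoms=(kingdoms[pair[0]], kingdoms[pair[1]]),
            n_snow_free=len(by_cond[SNOW_FREE]),
            n_snow_covered=len(by_cond[SNOW_COVERED]),
            signs_snow_free=by_cond[SNOW_FREE],
            signs_snow_covered=by_cond[SNOW_COVERED],
        )
    return records


def frequent_associations(
    networks: list[AssociationNetwork],
    min_networks: int = DEFAULT_MIN_NETWORKS,
    fb_only: bool = False,
) -> list[AssociationRecord]:
    """Associations present in at least ``min_networks`` networks of at least
    one condition (counts are per condition, never pooled)."""
    if min_networks < 1:
        raise ValueError("min_networks must be ≥ 1")
    records = tally_associations(networks)
    out = [
        r
        for r in records.values()
        if (r.n_snow_free >= min_networks or r.n_snow_covered >= min_networks)
        and (r.is_fb or not fb_only)
    ]
    return sorted(out, key=lambda r: r.pair)


def condition_specificity(
    records: list[AssociationRecord], min_networks: int = DEFAULT_MIN_NETWORKS
) -> dict[str, list[AssociationRecord]]:
    """Partition frequent associations into snow-free-only / snow-covered-only
    / both, judged by per-condition frequency."""
    out = {"snow-free-only": [], "snow-covered-only": [], "both": []}
    for r in records:
        in_free = r.frequent_in(SNOW_FREE, min_networks)
        in_cov = r.frequent_in(SNOW_COVERED, min_networks)
        if in_free and in_cov:
            out["both"].append(r)
        elif in_free:
            out["snow-free-only"].append(r)
        elif in_cov:
            out["snow-covered-only"].append(r)
    return out


def genus_summary(
    records: list[AssociationRecord],
    taxonomy: Taxonomy,
    min_pair_support: int = 2,
    min_networks: int = DEFAULT_MIN_NETWORKS,
) -> pd.DataFrame:
    """Genus-level summary of frequent fungal–bacterial associations.

    Per condition, fb records frequent in that condition are kept only when
    both partners carry a genus annotation, grouped by (fungal genus,
    bacterial genus), and genus pairs supported by fewer than
    ``min_pair_support`` ASV-level associations are dropped.  The consensus
    sign is the majority over the member associations' per-network signs.
    """
    if min_pair_support < 1:
        raise ValueError("min_pair_support must be ≥ 1")
    rows = []
    for condition in CONDITIONS:
        groups: dict[tuple[str, str], list[AssociationRecord]] = defaultdict(list)
        for r in records:
            if not r.is_fb or not r.frequent_in(condition, min_networks):
                continue
            fungal_id = r.pair[0] if r.kingdoms[0] == FUNGI else r.pair[1]
            bacterial_id = r.pair[1] if r.kingdoms[1] == BACTERIA else r.pair[0]
            f_genus = taxonomy.genus(fungal_id)
            b_genus = taxonomy.genus(bacterial_id)
            if f_genus is None or b_genus is None:
                continue
            groups[(f_genus, b_genus)].append(r)
        for (f_genus, b_genus), members in sorted(groups.items()):
            if len(members) < min_pair_support:
                continue
            signs = [
                s
                for m in members
                for s in (m.signs_snow_free if condition == SNOW_FREE else m.signs_snow_covered)
            ]
            pos = sum(1 for s in signs if s > 0)
            rows.append(
                {
                    "condition": condition,
                    "fungal_genus": f_genus,
                    "bacterial_genus": b_genus,
                    "n_supporting": len(members),
                    "consensus_sign": _consensus(signs),
                    "fraction_positive": pos / len(signs) if signs else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "fungal_genus", "bacterial_genus",
            "n_supporting", "consensus_sign", "fraction_positive",
        ],
    )


@dataclass
class RecoveryScore:
    condition: str
    precision: float | None  # None when nothing was detected
    recall: float
    sign_accuracy: float | None  # None when no true positives
    n_detected: int
    n_truth: int
    n_true_positive: int


def recovery_score(
    records: list[AssociationRecord],
    truth: SyntheticTruth,
    min_networks: int = DEFAULT_MIN_NETWORKS,
) -> dict[str, RecoveryScore]:
    """Precision/recall/sign accuracy of frequent fb associations against the
    planted truth, per condition."""
    if not truth.edges:
        raise ValueError("empty truth")
    truth_signs = {
        frozenset((e.fungal_id, e.bacterial_id)): e.sign for e in truth.edges
    }
    out = {}
    for condition in CONDITIONS:
        expected = truth_edge_set(truth, condition)
        detected = {
            frozenset(r.pair): r
            for r in records
            if r.is_fb and r.frequent_in(condition, min_networks)
        }
        tp_keys = set(detected) & expected
        recall = len(tp_keys) / len(expected) if expected else float("nan")
        precision = len(tp_keys) / len(detected) if detected else None
        sign_ok = None
        if tp_keys:
            agree = 0
            for key in tp_keys:
                r = detected[key]
                signs = r.signs_snow_free if condition == SNOW_FREE else r.signs_snow_covered
                if _consensus(signs) == ("+" if truth_signs[key] > 0 else "-"):
                    agree += 1
            sign_ok = agree / len(tp_keys)
        out[condition] = RecoveryScore(
            condition=condition,
            precision=precision,
            recall=recall,
            sign_accuracy=sign_ok,
            n_detected=len(detected),
            n_truth=len(expected),
            n_true_positive=len(tp_keys),
        )
    return out


def records_table(
    records: list[AssociationRecord], taxonomy: Taxonomy | None = None
) -> pd.DataFrame:
    """Tidy frame of association records (for TSV export)."""
    rows = []
    for r in records:
        row = {
            "asv_a": r.pair[0],
            "asv_b": r.pair[1],
            "kingdom_a": r.kingdoms[0],
            "kingdom_b": r.kingdoms[1],
            "n_snow_free": r.n_snow_free,
            "n_snow_covered": r.n_snow_covered,
            "consensus_sign": r.consensus_sign,
            "fraction_positive": r.fraction_positive,
        }
        if taxonomy is not None:
            row["genus_a"] = taxonomy.genus(r.pair[0], default="NA")
            row["genus_b"] = taxonomy.genus(r.pair[1], default="NA")
        rows.append(row)
    return pd.DataFrame(rows)
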