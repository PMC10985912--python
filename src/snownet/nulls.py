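"""Random-network null models for edge-type frequencies and shared edges.

Each inferred network is compared against uniformly random graphs: the same
node pool (every ASV of the filtered dataset, not only connected nodes) and
exactly the same edge count, with edges drawn uniformly among distinct node
pairs.  Replicated 999 times (default) this gives reference distributions
for the fungal-fungal / fungal-bacterial / bacterial-bacterial edge-type
fractions, and — drawing one random network per condition — for the number
of edges a snow-free and a snow-covered network share by chance.

The fb-restricted variant draws only fungal–bacterial pairs from the nodes
actually connected in each network; with far fewer candidate pairs, the
chance level of shared associations is markedly higher, which answers
whether fb partners are kept or swapped between seasons.

Empirical p-values use the add-one rule (1 + #{replicate ≥ observed}) /
(1 + R), so they are never zero; they are a convenience on top of the
purely distributional comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .inference import AssociationNetwork
from .metrics import edge_type_partition
from .tables import BACTERIA, FUNGI

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Null replicate distribution for one statistic of one network."""

    network_id: str
    statistic: str  # ff_frac | fb_frac | bb_frac | shared_total | shared_fb
    observed: float
    replicates: np.ndarray
    p_enrichment: float = field(init=False)
    p_depletion: float = field(init=False)

    def __post_init__(self) -> None:
        r = len(self.replicates)
        self.p_enrichment = (1 + int((self.replicates >= self.observed).sum())) / (1 + r)
        self.p_depletion = (1 + int((self.replicates <= self.observed).sum())) / (1 + r)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    def summary_row(self) -> dict:
        return {
            "network_id": self.network_id,
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "n_replicates": len(self.replicates),
        }


def _sample_pair_indices(rng: np.random.Generator, n_pairs: int, k: int) -> np.ndarray:
    """k distinct integers from [0, n_pairs) — distinct unordered node pairs."""
    if k > n_pairs:
        raise ValueError(f"cannot draw {k} distinct edges from {n_pairs} possible pairs")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > n_pairs // 3:
        return rng.permutation(n_pairs)[:k]
    chosen: set[int] = set()
    while len(chosen) < k:
        # rejection sampling: add uniform draws one by one, never trimming,
        # so every retained index is an unbiased uniform draw
        for v in rng.integers(0, n_pairs, size=k - len(chosen)):
            chosen.add(int(v))
            if len(chosen) == k:
                break
    return np.fromiter(chosen, dtype=np.int64, count=k)


def _decode_pairs(idx: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices to (i, j) with i<j over the m-node upper triangle."""
    # row i starts at offset i*m - i*(i+1)/2 - (i+1) pairs before it... use direct inversion
    i = (m - 2 - np.floor(np.sqrt(-8.0 * idx + 4.0 * m * (m - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
    j = (idx + i + 1 - (i * (2 * m - i - 1)) // 2).astype(np.int64)
    return i, j


def random_network(
    nodes: list[str],
    kingdoms: dict[str, str] | None,
    n_edges: int,
    rng: np.random.Generator | int | None = None,
) -> set[frozenset[str]]:
    """A uniform random edge set: ``n_edges`` distinct unordered pairs of
    ``nodes``, no self-loops."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = len(nodes)
    n_pairs = math.comb(m, 2)
    idx = _sample_pair_indices(rng, n_pairs, n_edges)
    i, j = _decode_pairs(idx, m)
    return {frozenset((nodes[a], nodes[b])) for a, b in zip(i, j)}


def _edge_type_fractions(i, j, is_fungus: np.ndarray) -> tuple[float, float, float]:
    fi, fj = is_fungus[i], is_fungus[j]
    n = len(i)
    if n == 0:
        return 0.0, 0.0, 0.0
    ff = int((fi & fj).sum())
    bb = int((~fi & ~fj).sum())
    return ff / n, (n - ff - bb) / n, bb / n


def edge_type_null(
    net: AssociationNetwork,
    dataset_nodes: dict[str, list[str]] | None = None,
    n_replicates: int = 999,
    seed: int | None = None,
) -> list[NullDistribution]:
    """Null distributions of ff/fb/bb edge fractions for one network.

    Random networks use the full filtered-dataset node pool with the
    network's observed edge count.
    """
    if dataset_nodes is None:
        dataset_nodes = net.dataset_nodes
    nodes = list(dataset_nodes.get(FUNGI, [])) + list(dataset_nodes.get(BACTERIA, []))
    is_fungus = np.array(
        [True] * len(dataset_nodes.get(FUNGI, [])) + [False] * len(dataset_nodes.get(BACTERIA, []))
    )
    m = len(nodes)
    n_edges = net.n_edges
    parts = edge_type_partition(net)
    observed = {
        "ff_frac": len(parts["ff"]) / n_edges if n_edges else 0.0,
        "fb_frac": len(parts["fb"]) / n_edges if n_edges else 0.0,
        "bb_frac": len(parts["bb"]) / n_edges if n_edges else 0.0,
    }
    rng = np.random.default_rng(seed)
    reps = {k: np.empty(n_replicates) for k in observed}
    n_pairs = math.comb(m, 2)
    for r in range(n_replicates):
        idx = _sample_pair_indices(rng, n_pairs, n_edges)
        i, j = _decode_pairs(idx, m)
        ff, fb, bb = _edge_type_fractions(i, j, is_fungus)
        reps["ff_frac"][r], reps["fb_frac"][r], reps["bb_frac"][r] = ff, fb, bb
    return [
        NullDistribution(net.label(), stat, observed[stat], reps[stat]) for stat in observed
    ]


def _connected_fb_nodes(net: AssociationNetwork) -> tuple[list[str], list[str]]:
    fungi = [v for v, d in net.graph.nodes(data=True) if d["kingdom"] == FUNGI]
    bacteria = [v for v, d in net.graph.nodes(data=True) if d["kingdom"] == BACTERIA]
    return fungi, bacteria


def shared_null(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    n_replicates: int = 999,
    seed: int | None = None,
    fb_restricted: bool = False,
) -> NullDistribution:
    """Null distribution of the number of edges two networks share by chance.

    Per replicate one random network is drawn per condition and the overlap
    counted.  In the default mode each draw uses the full filtered-dataset
    node pool and the network's total edge count; in ``fb_restricted`` mode
    only fungal–bacterial pairs among each network's *connected* fungal and
    bacterial nodes are drawn, matching that network's fb edge count.
    """
    rng = np.random.default_rng(seed)
    if fb_restricted:
        pools = []
        for net in (net_a, net_b):
            fungi, bacteria = _connected_fb_nodes(net)
            n_fb = len(edge_type_partition(net)["fb"])
            pools.append((fungi, bacteria, n_fb))
        observed = len(edge_type_partition(net_a)["fb"] & edge_type_partition(net_b)["fb"])
        statistic = "shared_fb"
    else:
        pools = []
        for net in (net_a, net_b):
            nodes = list(net.dataset_nodes.get(FUNGI, [])) + list(
                net.dataset_nodes.get(BACTERIA, [])
            )
            pools.append((nodes, None, net.n_edges))
        observed = len(net_a.edges & net_b.edges)
        statistic = "shared_total"

    reps = np.empty(n_replicates, dtype=np.int64)
    for r in range(n_replicates):
        sets = []
        for (first, second, k) in pools:
            if fb_restricted:
                n_pairs = len(first) * len(second)
                if k > n_pairs:
                    raise ValueError("more fb edges than candidate fb pairs")
                idx = _sample_pair_indices(rng, n_pairs, k)
                fi, bi = idx // max(len(second), 1), idx % max(len(second), 1)
                sets.append({frozenset((first[a], second[b])) for a, b in zip(fi, bi)})
            else:
                sets.append(random_network(first, None, k, rng))
        reps[r] = len(sets[0] & sets[1])
    label = f"{net_a.label()}|{net_b.label()}"
    return NullDistribution(label, statistic, float(observed), reps.astype(float))


def null_summary_table(dists: list[NullDistribution]) -> pd.DataFrame:
    return pd.DataFrame([d.summary_row() for d in dists])
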