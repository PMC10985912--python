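"""Per-network properties and paired snow-free/snow-covered comparisons.

"Longest path" is reported as the unweighted diameter (maximum eccentricity)
of the largest connected component — computing a true longest simple path is
NP-hard and the diameter is what standard graph libraries provide.  Density
is edges over possible node pairs; the fungal–bacterial (fb) density uses
the bipartite pair count of the *connected* fungal and bacterial nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .inference import AssociationNetwork
from .tables import BACTERIA, FUNGI

logger = logging.getLogger(__name__)

EDGE_TYPES = ("ff", "fb", "bb")


@dataclass
class NetworkProperties:
    """Summary statistics of one inferred network."""

    condition: str | None
    t_f: int | None
    t_b: int | None
    n_fungi_dataset: int
    n_bacteria_dataset: int
    n_fungi_net: int
    n_bacteria_net: int
    n_nodes: int
    n_edges: int
    n_ff: int
    n_fb: int
    n_bb: int
    n_positive: int
    n_negative: int
    density: float
    fb_density: float
    longest_path: int
    odds_positive: float  # inf when no negative edges

    def as_dict(self) -> dict:
        return asdict(self)


def edge_type_partition(net: AssociationNetwork) -> dict[str, set[frozenset[str]]]:
    """Partition edges into fungal-fungal (ff), fungal-bacterial (fb) and
    bacterial-bacterial (bb) sets."""
    out: dict[str, set[frozenset[str]]] = {t: set() for t in EDGE_TYPES}
    for a, b in net.graph.edges:
        ka = net.graph.nodes[a].get("kingdom")
        kb = net.graph.nodes[b].get("kingdom")
        if ka not in (FUNGI, BACTERIA) or kb not in (FUNGI, BACTERIA):
            raise ValueError(f"edge ({a}, {b}) has untagged node kingdom ({ka}, {kb})")
        kinds = {ka, kb}
        if kinds == {FUNGI}:
            out["ff"].add(frozenset((a, b)))
        elif kinds == {BACTERIA}:
            out["bb"].add(frozenset((a, b)))
        else:
            out["fb"].add(frozenset((a, b)))
    return out


def properties(
    net: AssociationNetwork,
    n_fungi_dataset: int | None = None,
    n_bacteria_dataset: int | None = None,
) -> NetworkProperties:
    """Compute all per-network properties.

    Dataset sizes default to the node pools recorded on the network (the
    post-filter inputs to inference, including later orphans).
    """
    g = net.graph
    if n_fungi_dataset is None:
        n_fungi_dataset = len(net.dataset_nodes.get(FUNGI, []))
    if n_bacteria_dataset is None:
        n_bacteria_dataset = len(net.dataset_nodes.get(BACTERIA, []))
    kingdoms = nx.get_node_attributes(g, "kingdom")
    n_fungi_net = sum(1 for k in kingdoms.values() if k == FUNGI)
    n_bacteria_net = sum(1 for k in kingdoms.values() if k == BACTERIA)
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    parts = edge_type_partition(net)
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    density = n_edges / math.comb(n_nodes, 2) if n_nodes >= 2 else 0.0
    fb_pairs = n_fungi_net * n_bacteria_net
    fb_density = len(parts["fb"]) / fb_pairs if fb_pairs else 0.0
    if n_nodes == 0:
        longest = 0
    else:
        biggest = max(nx.connected_components(g), key=len)
        longest = nx.diameter(g.subgraph(biggest)) if len(biggest) > 1 else 0
    if n_neg == 0:
        odds = math.inf
        if n_pos:
            logger.warning("network %s has no negative edges; odds_positive = inf", net.label())
    else:
        odds = n_pos / n_neg
    return NetworkProperties(
        condition=net.condition,
        t_f=net.pair.t_f if net.pair else None,
        t_b=net.pair.t_b if net.pair else None,
        n_fungi_dataset=n_fungi_dataset,
        n_bacteria_dataset=n_bacteria_dataset,
        n_fungi_net=n_fungi_net,
        n_bacteria_net=n_bacteria_net,
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_ff=len(parts["ff"]),
        n_fb=len(parts["fb"]),
        n_bb=len(parts["bb"]),
        n_positive=n_pos,
        n_negative=n_neg,
        density=density,
        fb_density=fb_density,
        longest_path=longest,
        odds_positive=odds,
    )


def properties_table(nets: list[AssociationNetwork]) -> pd.DataFrame:
    return pd.DataFrame([properties(n).as_dict() for n in nets])


def shared_edges(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    fb_only: bool = False,
    require_sign_agreement: bool = False,
) -> tuple[set[frozenset[str]], float, float]:
    """Edges detected in both networks and each network's shared fraction.

    Edge identity is the unordered ASV-id pair; weight and sign are ignored
    unless ``require_sign_agreement`` (strict mode).  ``fb_only`` restricts
    both networks to fungal–bacterial edges first.
    """
    if fb_only:
        edges_a = edge_type_partition(net_a)["fb"]
        edges_b = edge_type_partition(net_b)["fb"]
    else:
        edges_a, edges_b = net_a.edges, net_b.edges
    shared = edges_a & edges_b
    if require_sign_agreement:
        shared = {
            e for e in shared
            if net_a.edge_sign(*sorted(e)) == net_b.edge_sign(*sorted(e))
        }
    frac_a = len(shared) / len(edges_a) if edges_a else 0.0
    frac_b = len(shared) / len(edges_b) if edges_b else 0.0
    return shared, frac_a, frac_b


def paired_property_test(
    snow_free: np.ndarray | pd.Series,
    snow_covered: np.ndarray | pd.Series,
    method: str = "wilcoxon",
) -> float:
    """Paired test of a network property across the filter grid.

    The default is the Wilcoxon signed-rank test on the per-filter-pair
    differences (zero differences dropped); ``method="kruskal"`` instead
    pools the two conditions' values into an unpaired Kruskal–Wallis test.
    """
    x = np.asarray(snow_free, dtype=float)
    y = np.asarray(snow_covered, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if method == "kruskal":
        return float(stats.kruskal(x, y).pvalue)
    if method != "wilcoxon":
        raise ValueError("method must be 'wilcoxon' or 'kruskal'")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if len(nonzero) < 3:
        raise ValueError(
            f"only {len(nonzero)} non-zero paired differences; signed-rank test undefined"
        )
    return float(stats.wilcoxon(nonzero, zero_method="wilcox").pvalue)


def paired_comparison_table(
    props: pd.DataFrame,
    properties_to_test: tuple[str, ...] = (
        "n_nodes", "n_edges", "density", "fb_density", "n_ff", "n_fb", "n_bb",
        "longest_path",
    ),
) -> pd.DataFrame:
    """Wilcoxon signed-rank p-values for each property across the grid.

    ``props`` is the output of :func:`properties_table` covering both
    conditions; rows are matched on (t_f, t_b).
    """
    wide = props.pivot(index=["t_f", "t_b"], columns="condition", values=list(properties_to_test))
    rows = []
    for prop in properties_to_test:
        x = wide[(prop, "snow-free")].to_numpy()
        y = wide[(prop, "snow-covered")].to_numpy()
        finite = np.isfinite(x) & np.isfinite(y)
        try:
            p = paired_property_test(x[finite], y[finite])
        except ValueError as exc:
            logger.warning("paired test for %s skipped: %s", prop, exc)
            p = float("nan")
        rows.append(
            {
                "property": prop,
                "median_snow_free": float(np.nanmedian(x)),
                "median_snow_covered": float(np.nanmedian(y)),
                "p_wilcoxon": p,
            }
        )
    return pd.DataFrame(rows)
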