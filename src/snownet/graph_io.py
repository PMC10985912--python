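"""Network serialization: edge-list TSV plus a JSON sidecar.

The TSV holds one row per association (ids, kingdoms, weight, sign); the
sidecar records condition, filter thresholds, the selected penalty with its
instability path, and the full node pools that entered inference (needed by
the null models).  GraphML export is available for graph tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .filtering import FilterPair
from .inference import AssociationNetwork
from .tables import BACTERIA, FUNGI

EDGE_COLUMNS = ("id_a", "id_b", "kingdom_a", "kingdom_b", "weight", "sign")


def write_network(net: AssociationNetwork, edge_path: str | Path) -> Path:
    """Write ``<edge_path>`` (TSV) and ``<edge_path>.json`` (sidecar)."""
    edge_path = Path(edge_path)
    rows = []
    for a, b, d in sorted(net.graph.edges(data=True)):
        rows.append(
            {
                "id_a": a,
                "id_b": b,
                "kingdom_a": net.kingdom_of(a),
                "kingdom_b": net.kingdom_of(b),
                "weight": d["weight"],
                "sign": d["sign"],
            }
        )
    pd.DataFrame(rows, columns=list(EDGE_COLUMNS)).to_csv(edge_path, sep="\t", index=False)
    sidecar = {
        "condition": net.condition,
        "t_f": net.pair.t_f if net.pair else None,
        "t_b": net.pair.t_b if net.pair else None,
        "lambda_selected": net.lambda_selected,
        "instability_path": net.instability_path,
        "dataset_nodes": {k: list(v) for k, v in net.dataset_nodes.items()},
    }
    sidecar_path = edge_path.with_suffix(edge_path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return edge_path


def read_network(edge_path: str | Path) -> AssociationNetwork:
    edge_path = Path(edge_path)
    sidecar = json.loads(edge_path.with_suffix(edge_path.suffix + ".json").read_text())
    graph = nx.Graph()
    df = pd.read_csv(edge_path, sep="\t")
    for r in df.itertuples():
        graph.add_node(r.id_a, kingdom=r.kingdom_a)
        graph.add_node(r.id_b, kingdom=r.kingdom_b)
        graph.add_edge(r.id_a, r.id_b, weight=float(r.weight), sign=int(r.sign))
    pair = None
    if sidecar.get("t_f") is not None:
        pair = FilterPair(int(sidecar["t_f"]), int(sidecar["t_b"]))
    return AssociationNetwork(
        graph=graph,
        condition=sidecar.get("condition"),
        pair=pair,
        lambda_selected=sidecar.get("lambda_selected"),
        instability_path=[tuple(x) for x in sidecar.get("instability_path", [])],
        dataset_nodes={k: list(v) for k, v in sidecar.get("dataset_nodes", {}).items()},
    )


def write_graphml(net: AssociationNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
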