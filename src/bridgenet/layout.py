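"""Force-directed network layout and file exports.

The Fruchterman-Reingold layout treats |edge weight| as the attraction
multiplier (sign is rendered by colour, not geometry) and rescales the
final coordinates to the unit square.  Layout never feeds back into any
analysis number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bridge import BridgeTable, cross_community_edges
from .ggm import EDGE_EPS, PartialCorrelationNetwork

__all__ = ["NetworkLayout", "to_graph", "fruchterman_reingold", "export_network"]


@dataclass
class NetworkLayout:
    labels: list
    coordinates: np.ndarray  # p x 2, in [0, 1]^2
    iterations: int
    seed: int

    def __getitem__(self, label):
        return tuple(self.coordinates[self.labels.index(label)])


def to_graph(net: PartialCorrelationNetwork) -> nx.Graph:
    """networkx graph with signed ``weight`` and ``abs_weight`` attributes."""
    G = nx.Graph()
    for l in net.labels:
        G.add_node(l, community=net.community_of_node.get(l, ""))
    p = net.p
    for i in range(p):
        for j in range(i + 1, p):
            w = float(net.weights[i, j])
            if abs(w) > EDGE_EPS:
                G.add_edge(net.labels[i], net.labels[j], weight=w, abs_weight=abs(w))
    return G


def fruchterman_reingold(
    net: PartialCorrelationNetwork, iterations=500, seed=0
) -> NetworkLayout:
    """Deterministic Fruchterman-Reingold layout in the unit square."""
    if net.p < 1:
        raise ValueError("layout needs at least one node")
    G = to_graph(net)
    pos = nx.spring_layout(
        G, weight="abs_weight", iterations=iterations, seed=int(seed)
    )
    coords = np.array([pos[l] for l in net.labels], dtype=float)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    coords = (coords - lo) / span
    coords[:, np.asarray(hi - lo == 0)] = 0.5
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("layout produced non-finite coordinates")
    return NetworkLayout(
        labels=list(net.labels),
        coordinates=coords,
        iterations=iterations,
        seed=int(seed),
    )


def export_network(
    net: PartialCorrelationNetwork,
    bridge_table: BridgeTable | None = None,
    layout: NetworkLayout | None = None,
    out_dir=".",
) -> dict:
    """Write node table, edge table, full weight matrix and a GraphML file.

    Numeric values are written at full (repr) precision so the weight
    matrix round-trips bit-exactly through
    ``pandas.read_csv(..., float_precision="round_trip")``.
    Returns the mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    nodes = pd.DataFrame(index=pd.Index(net.labels, name="node"))
    nodes["community"] = [net.community_of_node.get(l, "") for l in net.labels]
    if bridge_table is not None:
        nodes["bei"] = bridge_table.bei
    if layout is not None:
        nodes["x"] = layout.coordinates[:, 0]
        nodes["y"] = layout.coordinates[:, 1]
    paths["nodes"] = out / "nodes.csv"
    nodes.to_csv(paths["nodes"], float_format=None)

    comm = net.community_of_node
    rows = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = float(net.weights[i, j])
            if abs(w) > EDGE_EPS:
                a, b = net.labels[i], net.labels[j]
                rows.append(
                    {
                        "node_a": a,
                        "node_b": b,
                        "weight": w,
                        "is_cross_community": comm.get(a) != comm.get(b),
                    }
                )
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "is_cross_community"])
    paths["edges"] = out / "edges.csv"
    edges.to_csv(paths["edges"], index=False)

    paths["weights"] = out / "weights.csv"
    net.to_dataframe().to_csv(paths["weights"])

    paths["graphml"] = out / "network.graphml"
    nx.write_graphml(to_graph(net), paths["graphml"])
    return paths
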