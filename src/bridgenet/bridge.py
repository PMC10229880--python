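"""Bridge centrality over a two-community (or k-community) node partition.

Bridge expected influence (BEI) of a node is the signed sum of its edge
weights to all nodes outside its own community — the 1-step, unnormalized
variant.  Nodes with high BEI are the candidate comorbidity bridges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ggm import EDGE_EPS, PartialCorrelationNetwork

__all__ = [
    "BridgeTable",
    "CrossCommunityEdgeList",
    "bridge_expected_influence",
    "cross_community_edges",
    "select_bridge_nodes",
]


@dataclass
class BridgeTable:
    """Per-node bridge expected influence and its percentile rank."""

    node_labels: list
    bei: np.ndarray
    percentile_rank: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bei": self.bei, "percentile_rank": self.percentile_rank},
            index=self.node_labels,
        )

    def __getitem__(self, label) -> float:
        return float(self.bei[self.node_labels.index(label)])


@dataclass
class CrossCommunityEdgeList:
    """Nonzero edges whose endpoints lie in different communities.

    ``positive_share`` is ``100 * positive / total`` or ``None`` when there
    are no cross-community edges (undefined, not zero).
    ``max_possible`` is the bipartite bound |C1| x |C2| summed over
    community pairs.
    """

    edges: list  # (node_a, node_b, weight), |weight| descending
    total: int
    positive: int
    negative: int
    max_possible: int

    @property
    def positive_share(self):
        if self.total == 0:
            return None
        return 100.0 * self.positive / self.total

    def weight_range(self):
        if not self.edges:
            return None
        w = [e[2] for e in self.edges]
        return (min(w), max(w))


def _check_communities(net: PartialCorrelationNetwork):
    missing = [l for l in net.labels if l not in net.community_of_node]
    if missing:
        raise ValueError(f"node(s) without community assignment: {missing}")
    return np.array([net.community_of_node[l] for l in net.labels])


def bridge_expected_influence(net: PartialCorrelationNetwork) -> BridgeTable:
    """BEI_i = sum over j with community(j) != community(i) of w_ij.

    The sum is signed and unnormalized; within-community edges never
    contribute.  Percentile ranks are the mean-kind empirical percentiles
    of the BEI values among the network's nodes.
    """
    comm = _check_communities(net)
    other = comm[:, None] != comm[None, :]
    bei = (net.weights * other).sum(axis=1)
    # mean-kind percentile rank of each value among all p values
    less = (bei[None, :] < bei[:, None]).sum(axis=1)
    equal = (bei[None, :] == bei[:, None]).sum(axis=1)
    rank = 100.0 * (less + 0.5 * equal) / len(bei)
    return BridgeTable(node_labels=list(net.labels), bei=bei, percentile_rank=rank)


def cross_community_edges(net: PartialCorrelationNetwork) -> CrossCommunityEdgeList:
    """Enumerate strictly nonzero cross-community edges, |weight| descending."""
    comm = _check_communities(net)
    p = net.p
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if comm[i] != comm[j] and abs(net.weights[i, j]) > EDGE_EPS:
                edges.append((net.labels[i], net.labels[j], float(net.weights[i, j])))
    edges.sort(key=lambda e: abs(e[2]), reverse=True)
    pos = sum(1 for e in edges if e[2] > 0)
    neg = sum(1 for e in edges if e[2] < 0)
    sizes = pd.Series(comm).value_counts()
    max_possible = int(
        sum(
            sizes.iloc[a] * sizes.iloc[b]
            for a in range(len(sizes))
            for b in range(a + 1, len(sizes))
        )
    )
    return CrossCommunityEdgeList(
        edges=edges,
        total=len(edges),
        positive=pos,
        negative=neg,
        max_possible=max_possible,
    )


def select_bridge_nodes(table: BridgeTable, percentile=80.0) -> list:
    """Nodes whose BEI is at or above the empirical percentile of all BEIs.

    The threshold is the linear-interpolation quantile of the node BEI
    values; selection uses >=, so exact ties with the threshold are kept.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    thr = np.percentile(table.bei, percentile, method="linear")
    return [l for l, b in zip(table.node_labels, table.bei) if b >= thr]
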