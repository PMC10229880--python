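"""Synthetic Likert cohorts from a planted two-community partial-correlation
network.

The generator emulates a pediatric anxiety / internet-gaming-disorder
survey: 5 anxiety-dimension nodes (sums of 0-3 items) and 9 IGD item nodes
(coded 1-5).  Latent scores are multivariate normal with a known sparse
partial-correlation structure; observed Likert scores are obtained by
rounding and clipping a location/scale transform of each latent margin,
with the location and scale calibrated so the discretized node means and
SDs match the preset targets as closely as the discrete support allows.

The default planted structure has 23 cross-community edges (20 positive,
3 negative, weights -0.03 to 0.12) and three designated bridge nodes
(A2, A3, IGD5); within-community edges sit on a sparse seeded backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bridge import bridge_expected_influence, select_bridge_nodes
from .ggm import EDGE_EPS, PartialCorrelationNetwork, precision_to_pcor
from .scoring import NodeScoreTable

__all__ = [
    "TrueNetworkSpec",
    "SyntheticCohort",
    "RecoveryMetrics",
    "DEFAULT_CROSS_EDGES",
    "DEFAULT_NODE_MOMENTS",
    "make_true_network",
    "simulate_cohort",
    "recovery_metrics",
]

ANXIETY_NODES = ("A1", "A2", "A3", "A4", "A5")
IGD_NODES = tuple(f"IGD{i}" for i in range(1, 10))
DEFAULT_LABELS = ANXIETY_NODES + IGD_NODES

#: default planted cross-community partial correlations (23 edges)
DEFAULT_CROSS_EDGES = (
    ("A1", "IGD3", 0.04),
    ("A1", "IGD5", 0.02),
    ("A1", "IGD6", -0.01),
    ("A1", "IGD9", 0.01),
    ("A2", "IGD1", 0.04),
    ("A2", "IGD2", 0.04),
    ("A2", "IGD3", 0.06),
    ("A2", "IGD4", 0.01),
    ("A2", "IGD6", 0.04),
    ("A2", "IGD8", 0.02),
    ("A3", "IGD5", 0.12),
    ("A3", "IGD6", 0.06),
    ("A3", "IGD7", 0.02),
    ("A3", "IGD9", 0.01),
    ("A4", "IGD5", 0.01),
    ("A4", "IGD6", -0.03),
    ("A4", "IGD8", -0.02),
    ("A5", "IGD1", 0.003),
    ("A5", "IGD4", 0.03),
    ("A5", "IGD5", 0.06),
    ("A5", "IGD6", 0.03),
    ("A5", "IGD8", 0.01),
    ("A5", "IGD9", 0.04),
)

#: default target (mean, SD) per node on the observed Likert scale
DEFAULT_NODE_MOMENTS = {
    "A1": (3.69, 2.43),
    "A2": (3.32, 2.35),
    "A3": (1.05, 1.84),
    "A4": (2.70, 2.29),
    "A5": (2.97, 2.50),
    "IGD1": (1.69, 1.05),
    "IGD2": (1.78, 1.08),
    "IGD3": (1.38, 0.83),
    "IGD4": (1.50, 0.89),
    "IGD5": (1.33, 0.81),
    "IGD6": (1.38, 0.82),
    "IGD7": (1.52, 1.00),
    "IGD8": (1.50, 0.95),
    "IGD9": (1.50, 0.99),
}

#: observed score support per node: anxiety dims are sums of 0-3 items
#: (dimension sizes 4,4,3,4,4), IGD items are raw 1-5 codes
DEFAULT_NODE_LEVELS = {
    "A1": (0, 12),
    "A2": (0, 12),
    "A3": (0, 9),
    "A4": (0, 12),
    "A5": (0, 12),
    **{f"IGD{i}": (1, 5) for i in range(1, 10)},
}

DEFAULT_COMMUNITIES = {
    **{a: "anxiety" for a in ANXIETY_NODES},
    **{g: "IGD" for g in IGD_NODES},
}


@dataclass
class TrueNetworkSpec:
    """Ground truth driving the generator.

    ``pcor`` is the exact planted partial-correlation matrix implied by the
    final (positive-definite) precision matrix; ``marginal_params`` holds
    the calibrated per-node (location, scale) of the discretization.
    """

    labels: list
    community_of_node: dict
    pcor: np.ndarray
    precision: np.ndarray
    sigma: np.ndarray  # latent correlation matrix
    node_levels: dict
    node_moments: dict
    marginal_params: dict
    shrink_factor: float = 1.0

    @property
    def p(self) -> int:
        return len(self.labels)

    def as_network(self) -> PartialCorrelationNetwork:
        """The true network as a PartialCorrelationNetwork (n is nominal)."""
        return PartialCorrelationNetwork(
            labels=list(self.labels),
            weights=self.pcor.copy(),
            community_of_node=dict(self.community_of_node),
            n=0,
        )

    def true_bei(self) -> np.ndarray:
        return bridge_expected_influence(self.as_network()).bei

    def bridge_nodes(self, percentile=80.0) -> list:
        return select_bridge_nodes(
            bridge_expected_influence(self.as_network()), percentile
        )

    def thresholds(self, label) -> np.ndarray:
        """Latent z-space cutpoints between adjacent observed levels."""
        lo, hi = self.node_levels[label]
        mu, sc = self.marginal_params[label]
        return (np.arange(lo, hi) + 0.5 - mu) / sc


@dataclass
class SyntheticCohort:
    scores: NodeScoreTable
    spec: TrueNetworkSpec
    seed: int
    latent: np.ndarray | None = None
    items: pd.DataFrame | None = None


@dataclass
class RecoveryMetrics:
    """How well an estimated network recovers the planted truth."""

    sensitivity: float
    specificity: float
    mae_true_edges: float
    bei_rank_correlation: float
    true_bridge_nodes: list
    estimated_bridge_nodes: list


def _sparse_backbone(nodes, rng, n_extra):
    """Random spanning tree over ``nodes`` plus ``n_extra`` extra edges."""
    nodes = list(nodes)
    edges = set()
    for i in range(1, len(nodes)):
        j = int(rng.integers(0, i))
        edges.add((nodes[j], nodes[i]))
    candidates = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if (nodes[i], nodes[j]) not in edges
    ]
    if n_extra > 0 and candidates:
        pick = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
        for k in np.atleast_1d(pick):
            edges.add(candidates[int(k)])
    return sorted(edges)


def _calibrate_marginal(lo, hi, target_mean, target_sd):
    """Location/scale of a rounded-and-clipped normal whose discretized
    mean and SD match the targets as closely as possible."""
    levels = np.arange(lo, hi + 1, dtype=float)
    cuts = levels[:-1] + 0.5

    def moments(x):
        mu, logsc = x
        sc = np.exp(logsc)
        cdf = stats.norm.cdf((cuts - mu) / sc)
        probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
        m = float(probs @ levels)
        v = float(probs @ (levels - m) ** 2)
        return m, np.sqrt(max(v, 1e-12))

    def resid(x):
        m, s = moments(x)
        return [m - target_mean, s - target_sd]

    x0 = np.array([target_mean, np.log(max(target_sd, 0.1))])
    sol = optimize.least_squares(resid, x0, xtol=1e-12, ftol=1e-12)
    mu, sc = float(sol.x[0]), float(np.exp(sol.x[1]))
    return mu, sc


def make_true_network(
    cross_edges=DEFAULT_CROSS_EDGES,
    within_weight=0.15,
    within_edges=None,
    backbone_seed=1234,
    node_moments=None,
    node_levels=None,
    labels=DEFAULT_LABELS,
    community_of_node=None,
) -> TrueNetworkSpec:
    """Build a positive-definite planted network specification.

    The precision matrix is ``K = I`` with ``K_ij = -P*_ij`` for every
    planted edge; if K is not positive definite, all off-diagonals are
    shrunk by a common factor (error if the factor would fall below 0.5)
    and the exact implied partial correlations are recomputed.
    """
    labels = list(labels)
    community_of_node = dict(community_of_node or DEFAULT_COMMUNITIES)
    node_moments = dict(node_moments or DEFAULT_NODE_MOMENTS)
    node_levels = dict(node_levels or DEFAULT_NODE_LEVELS)
    p = len(labels)
    idx = {l: i for i, l in enumerate(labels)}

    P = np.zeros((p, p))
    for a, b, w in cross_edges:
        if not -1 < w < 1:
            raise ValueError(f"planted weight out of (-1, 1): {(a, b, w)}")
        if community_of_node[a] == community_of_node[b]:
            raise ValueError(f"{(a, b)} is not a cross-community pair")
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w

    if within_edges is None:
        rng = np.random.default_rng(backbone_seed)
        within_edges = []
        comms = {}
        for l in labels:
            comms.setdefault(community_of_node[l], []).append(l)
        for members in comms.values():
            extra = max(len(members) // 4, 1)
            for a, b in _sparse_backbone(members, rng, extra):
                within_edges.append((a, b, within_weight))
    for a, b, w in within_edges:
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w

    shrink = 1.0
    while True:
        K = np.eye(p) - shrink * P
        if np.linalg.eigvalsh(K).min() > 1e-6:
            break
        shrink *= 0.95
        if shrink < 0.5:
            raise ValueError(
                "planted structure cannot be made positive definite by "
                "off-diagonal shrinkage >= 0.5"
            )
    exact_pcor = precision_to_pcor(K)

    Sig = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sig))
    Sig = Sig / np.outer(d, d)
    Sig = (Sig + Sig.T) / 2.0
    np.fill_diagonal(Sig, 1.0)

    marginal_params = {
        l: _calibrate_marginal(*node_levels[l], *node_moments[l]) for l in labels
    }
    return TrueNetworkSpec(
        labels=labels,
        community_of_node=community_of_node,
        pcor=exact_pcor,
        precision=K,
        sigma=Sig,
        node_levels=node_levels,
        node_moments=node_moments,
        marginal_params=marginal_params,
        shrink_factor=shrink,
    )


def simulate_cohort(
    spec: TrueNetworkSpec, n, seed, mode="node", item_loading=0.7, keep_latent=False
) -> SyntheticCohort:
    """Draw a cohort of n respondents from the planted network.

    ``mode="node"`` (default) generates the 14 node scores directly.
    ``mode="item"`` additionally generates item-level responses (19
    four-point anxiety items and 9 five-point IGD items) for exercising the
    scoring layer; anxiety items load on their dimension's latent score
    with ``item_loading`` and their sum approximates the node score.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = spec.p
    L = np.linalg.cholesky(spec.sigma)
    Z = rng.standard_normal((n, p)) @ L.T

    data = {}
    for j, label in enumerate(spec.labels):
        t = spec.thresholds(label)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"thresholds for {label} are not strictly increasing")
        lo, hi = spec.node_levels[label]
        mu, sc = spec.marginal_params[label]
        data[label] = np.clip(np.rint(mu + sc * Z[:, j]), lo, hi).astype(int)
    ids = [f"r{i+1:06d}" for i in range(n)]
    scores_df = pd.DataFrame(data, index=ids)

    items_df = None
    if mode == "item":
        from .scoring import igds, scas_short

        scas, ig = scas_short(), igds()
        cols = {}
        for dim, its in scas.dimensions.items():
            k = len(its)
            zdim = Z[:, spec.labels.index(dim)]
            m, s = spec.node_moments[dim]
            # per-item marginal chosen so the item sum tracks the node target
            r = item_loading**2
            item_sd = s / np.sqrt(k + k * (k - 1) * r)
            imu, isc = _calibrate_marginal(0, 3, m / k, item_sd)
            for it in its:
                zi = item_loading * zdim + np.sqrt(
                    1 - item_loading**2
                ) * rng.standard_normal(n)
                cols[it] = np.clip(np.rint(imu + isc * zi), 0, 3).astype(int)
        for dim, its in ig.dimensions.items():
            cols[its[0]] = scores_df[dim].to_numpy()
        items_df = pd.DataFrame(cols, index=ids)
    elif mode != "node":
        raise ValueError(f"unknown mode: {mode!r}")

    table = NodeScoreTable(
        scores=scores_df, community_of_node=dict(spec.community_of_node)
    )
    return SyntheticCohort(
        scores=table,
        spec=spec,
        seed=seed,
        latent=Z if keep_latent else None,
        items=items_df,
    )


def recovery_metrics(
    spec: TrueNetworkSpec, estimated: PartialCorrelationNetwork, percentile=80.0
) -> RecoveryMetrics:
    """Edge-set sensitivity/specificity, MAE on true-nonzero edges and the
    rank correlation between true and estimated BEI vectors."""
    if list(estimated.labels) != list(spec.labels):
        raise ValueError("estimated network labels do not match the planted spec")
    iu = np.triu_indices(spec.p, k=1)
    t = spec.pcor[iu]
    e = estimated.weights[iu]
    t_nz, e_nz = np.abs(t) > EDGE_EPS, np.abs(e) > EDGE_EPS
    sens = float(np.mean(e_nz[t_nz])) if t_nz.any() else np.nan
    spec_ = float(np.mean(~e_nz[~t_nz])) if (~t_nz).any() else np.nan
    mae = float(np.mean(np.abs(e[t_nz] - t[t_nz]))) if t_nz.any() else np.nan
    true_bei = spec.true_bei()
    est_table = bridge_expected_influence(estimated)
    if np.std(true_bei) == 0 or np.std(est_table.bei) == 0:
        rho = np.nan  # a constant BEI vector has no ranks to correlate
    else:
        rho = float(stats.spearmanr(true_bei, est_table.bei).statistic)
    return RecoveryMetrics(
        sensitivity=sens,
        specificity=spec_,
        mae_true_edges=mae,
        bei_rank_correlation=rho,
        true_bridge_nodes=spec.bridge_nodes(percentile),
        estimated_bridge_nodes=select_bridge_nodes(est_table, percentile),
    )
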