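"""statsmodels-style front end: a model object fitted to score data, a
results object carrying the selected network plus everything that hangs
off it (bridge centrality, bootstraps, layout, summary, plot)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bridge as _bridge
from . import ggm as _ggm
from . import robustness as _rob
from .layout import export_network, fruchterman_reingold
from .scoring import NodeScoreTable

__all__ = ["SymptomNetworkModel", "SymptomNetworkResults"]


class SymptomNetworkModel:
    """Regularized partial-correlation network model for symptom scores.

    Parameters
    ----------
    scores : DataFrame or NodeScoreTable
        Respondent x node score matrix.
    communities : mapping, optional
        ``node -> community`` partition; required for bridge statistics.
        Taken from the NodeScoreTable when one is given.

    Examples
    --------
    >>> model = SymptomNetworkModel.from_dataframe(df, communities)
    >>> res = model.fit(gamma=0.5)
    >>> res.bridge_table().to_dataframe()
    """

    def __init__(self, scores, communities=None):
        if isinstance(scores, NodeScoreTable):
            self.scores = scores.scores
            self.communities = dict(communities or scores.community_of_node)
        else:
            self.scores = pd.DataFrame(scores)
            self.communities = dict(communities or {})
        self.nobs = len(self.scores)
        self.labels = list(self.scores.columns)

    @classmethod
    def from_dataframe(cls, df, communities=None):
        return cls(df, communities)

    @classmethod
    def from_items(cls, responses, defs):
        """Build from item-level responses via the scoring layer."""
        from .scoring import score_scales

        return cls(score_scales(responses, defs))

    def fit(
        self,
        gamma=0.5,
        method="pearson",
        n_lambda=100,
        lambda_min_ratio=0.01,
        tol=1e-4,
        max_iter=1000,
    ) -> "SymptomNetworkResults":
        """Estimate the EBIC-selected graphical-lasso network."""
        fit_kwargs = dict(
            method=method,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            tol=tol,
            max_iter=max_iter,
        )
        net = _ggm.estimate_network(
            self.scores, self.communities, gamma=gamma, **fit_kwargs
        )
        return SymptomNetworkResults(self, net, gamma=gamma, fit_kwargs=fit_kwargs)


class SymptomNetworkResults:
    """Fitted symptom network: EBIC-selected edge weights and diagnostics."""

    def __init__(self, model, network, gamma, fit_kwargs):
        self.model = model
        self.network = network
        self.gamma = gamma
        self.fit_kwargs = dict(fit_kwargs)
        self.nobs = network.n

    # -- basic accessors ---------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.network.to_dataframe()

    @property
    def selected_lambda(self) -> float:
        return self.network.selected_lambda

    @property
    def edge_count(self) -> int:
        return self.network.edge_count

    # -- bridge centrality -------------------------------------------------
    def bridge_table(self) -> _bridge.BridgeTable:
        return _bridge.bridge_expected_influence(self.network)

    def cross_community_edges(self) -> _bridge.CrossCommunityEdgeList:
        return _bridge.cross_community_edges(self.network)

    def bridge_nodes(self, percentile=80.0) -> list:
        return _bridge.select_bridge_nodes(self.bridge_table(), percentile)

    # -- robustness --------------------------------------------------------
    def bootstrap_edges(self, B=1000, seed=None, ci_level=0.95):
        """Nonparametric bootstrap CIs for every edge (refits the network)."""
        return _rob.bootstrap_edge_ci(
            NodeScoreTable(self.model.scores, self.model.communities),
            B=B,
            gamma=self.gamma,
            seed=seed,
            ci_level=ci_level,
            **self.fit_kwargs,
        )

    def case_drop(self, grid=_rob.DEFAULT_DROP_GRID, B=1000, seed=None,
                  correlation="pearson"):
        """Case-dropping bootstrap of the BEI vector."""
        return _rob.case_drop_bootstrap(
            NodeScoreTable(self.model.scores, self.model.communities),
            grid=grid,
            B=B,
            gamma=self.gamma,
            seed=seed,
            correlation=correlation,
            **self.fit_kwargs,
        )

    # -- presentation ------------------------------------------------------
    def layout(self, iterations=500, seed=0):
        return fruchterman_reingold(self.network, iterations=iterations, seed=seed)

    def export(self, out_dir, layout_seed=0):
        return export_network(
            self.network,
            bridge_table=self.bridge_table(),
            layout=self.layout(seed=layout_seed),
            out_dir=out_dir,
        )

    def plot(self, ax=None, layout_seed=0):
        """Draw the network: blue positive edges, red negative, width ~ |w|."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        lay = self.layout(seed=layout_seed)
        net = self.network
        for i in range(net.p):
            for j in range(i + 1, net.p):
                w = net.weights[i, j]
                if abs(w) <= _ggm.EDGE_EPS:
                    continue
                xy = lay.coordinates[[i, j]]
                ax.plot(
                    xy[:, 0],
                    xy[:, 1],
                    color="tab:blue" if w > 0 else "tab:red",
                    linewidth=0.5 + 8 * abs(w),
                    alpha=min(1.0, 0.2 + 4 * abs(w)),
                    zorder=1,
                )
        comms = {c: k for k, c in enumerate(dict.fromkeys(net.community_of_node.values()))}
        colors = [f"C{comms.get(net.community_of_node.get(l), 0)}" for l in net.labels]
        ax.scatter(*lay.coordinates.T, s=450, c=colors, zorder=2, edgecolors="k")
        for l, (x, y) in zip(net.labels, lay.coordinates):
            ax.annotate(l, (x, y), ha="center", va="center", fontsize=7, zorder=3)
        ax.set_axis_off()
        return ax

    def summary(self) -> str:
        """Plain-text summary of the fitted network."""
        net = self.network
        bt = self.bridge_table()
        cc = self.cross_community_edges()
        lines = [
            "Symptom Network (graphical lasso, EBIC selection)",
            "=" * 55,
            f"Nodes:                 {net.p}",
            f"Observations:          {net.n}",
            f"Correlation input:     {net.correlation_method}",
            f"EBIC gamma:            {self.gamma}",
            f"Selected lambda:       {net.selected_lambda:.6g}",
            f"Nonzero edges:         {net.edge_count} / {net.p * (net.p - 1) // 2}",
            f"Cross-community edges: {cc.total} / {cc.max_possible}",
        ]
        if cc.positive_share is not None:
            lo, hi = cc.weight_range()
            lines.append(f"  positive share:      {cc.positive_share:.2f}%")
            lines.append(f"  weight range:        [{lo:.3g}, {hi:.3g}]")
        lines.append("-" * 55)
        lines.append("Bridge expected influence (descending):")
        order = np.argsort(bt.bei)[::-1]
        for k in order:
            lines.append(f"  {bt.node_labels[k]:<6} {bt.bei[k]: .4f}")
        return "\n".join(lines)
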