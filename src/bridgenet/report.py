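"""End-to-end pipeline: scoring -> network -> bridge -> robustness ->
layout -> export, driven by a single config mapping and one master seed.

The report is a plain JSON document that fully determines a re-run:
feeding ``report["config"]`` back into :func:`run_pipeline` reproduces the
same numbers byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import robustness as _rob
from .bridge import bridge_expected_influence, cross_community_edges, select_bridge_nodes
from .layout import export_network, fruchterman_reingold
from .model import SymptomNetworkModel
from .scoring import default_scales, load_item_responses, score_scales
from .synth import make_true_network, simulate_cohort

__all__ = ["AnalysisReport", "PipelineError", "run_pipeline", "bei_replicates"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisReport:
    """Machine-readable pipeline output."""

    payload: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.payload[key]

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=2)

    def save(self, path):
        Path(path).write_text(self.to_json() + "\n")


def bei_replicates(boot: "_rob.EdgeBootstrapResult", community_of_node) -> np.ndarray:
    """Per-replicate BEI vectors reconstructed from edge-weight replicates.

    Returns a B x p matrix in the order of the nodes appearing in
    ``boot.pairs``.
    """
    labels = []
    for a, b in boot.pairs:
        for l in (a, b):
            if l not in labels:
                labels.append(l)
    idx = {l: k for k, l in enumerate(labels)}
    B = boot.replicates.shape[0]
    out = np.zeros((B, len(labels)))
    for col, (a, b) in enumerate(boot.pairs):
        if community_of_node[a] != community_of_node[b]:
            out[:, idx[a]] += boot.replicates[:, col]
            out[:, idx[b]] += boot.replicates[:, col]
    return out


def _stage_seeds(master_seed):
    ss = np.random.SeedSequence(int(master_seed))
    state = ss.generate_state(4)
    names = ["synthetic", "edge_bootstrap", "case_drop", "layout"]
    return {k: int(v & 0x7FFFFFFF) for k, v in zip(names, state)}


def _resolve_config(config) -> dict:
    cfg = json.loads(json.dumps(config))  # deep copy, JSON-clean
    cfg.setdefault("seed", 0)
    cfg.setdefault("gamma", 0.5)
    cfg.setdefault("correlation_method", "pearson")
    cfg.setdefault("n_lambda", 100)
    cfg.setdefault("lambda_min_ratio", 0.01)
    cfg.setdefault("tol", 1e-4)
    cfg.setdefault("max_iter", 1000)
    cfg.setdefault("percentile", 80.0)
    cfg.setdefault("bootstrap", {})
    cfg["bootstrap"].setdefault("enabled", True)
    cfg["bootstrap"].setdefault("B", 1000)
    cfg.setdefault("case_drop", {})
    cfg["case_drop"].setdefault("enabled", True)
    cfg["case_drop"].setdefault("B", 1000)
    cfg["case_drop"].setdefault("grid", [float(q) for q in _rob.DEFAULT_DROP_GRID])
    cfg["case_drop"].setdefault("cor_threshold", 0.7)
    cfg["case_drop"].setdefault("prob", 0.95)
    cfg.setdefault("layout", {})
    cfg["layout"].setdefault("enabled", True)
    cfg["layout"].setdefault("iterations", 500)
    cfg.setdefault("stage_seeds", _stage_seeds(cfg["seed"]))
    if "input" not in cfg and "synthetic" not in cfg:
        raise ValueError("config needs an 'input' or a 'synthetic' section")
    if "synthetic" in cfg:
        cfg["synthetic"].setdefault("n", 1000)
        cfg["synthetic"].setdefault("mode", "node")
    return cfg


def run_pipeline(config) -> AnalysisReport:
    """Run the full analysis described by ``config`` and return the report.

    Every stochastic stage is seeded deterministically from ``config["seed"]``;
    the per-stage seeds are echoed in the report.
    """
    cfg = _resolve_config(config)
    seeds = cfg["stage_seeds"]
    payload = {"config": cfg, "warnings": []}
    caught: list = []

    def _run(stage, fn):
        try:
            with warnings.catch_warnings(record=True) as w:
                warnings.simplefilter("always")
                out = fn()
            for x in w:
                caught.append(f"{stage}: {x.message}")
            return out
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, exc) from exc

    # -- scoring / data ----------------------------------------------------
    def _load():
        if "input" in cfg:
            defs = default_scales()
            table = load_item_responses(
                cfg["input"]["path"], defs, id_column=cfg["input"].get("id_column")
            )
            scores = score_scales(table, defs)
            return scores, {"retention": table.retention, "n_dropped": table.n_dropped}
        syn = cfg["synthetic"]
        spec = make_true_network()
        cohort = simulate_cohort(
            spec, syn["n"], seed=syn.get("seed", seeds["synthetic"]), mode=syn["mode"]
        )
        if syn["mode"] == "item":
            defs = default_scales()
            return score_scales(load_item_responses(cohort.items, defs), defs), {}
        return cohort.scores, {}

    scores, meta = _run("scoring", _load)
    payload.update(meta)

    # -- network estimation ------------------------------------------------
    def _fit():
        model = SymptomNetworkModel(scores)
        return model.fit(
            gamma=cfg["gamma"],
            method=cfg["correlation_method"],
            n_lambda=cfg["n_lambda"],
            lambda_min_ratio=cfg["lambda_min_ratio"],
            tol=cfg["tol"],
            max_iter=cfg["max_iter"],
        )

    res = _run("estimate_network", _fit)
    net = res.network
    payload["n"] = net.n
    payload["nodes"] = list(net.labels)
    payload["communities"] = dict(net.community_of_node)
    payload["correlation_method"] = net.correlation_method
    payload["gamma"] = cfg["gamma"]
    payload["selected_lambda"] = float(net.selected_lambda)
    payload["edge_count"] = net.edge_count

    # -- bridge centrality -------------------------------------------------
    def _bridge():
        bt = bridge_expected_influence(net)
        cc = cross_community_edges(net)
        return bt, cc

    bt, cc = _run("bridge", _bridge)
    payload["edges"] = [
        {"node_a": a, "node_b": b, "weight": w} for a, b, w in _all_edges(net)
    ]
    payload["cross_community"] = {
        "total": cc.total,
        "positive": cc.positive,
        "negative": cc.negative,
        "max_possible": cc.max_possible,
        "positive_share": cc.positive_share,
        "edges": [{"node_a": a, "node_b": b, "weight": w} for a, b, w in cc.edges],
    }
    payload["bei"] = {l: float(v) for l, v in zip(bt.node_labels, bt.bei)}
    payload["bridge_nodes"] = select_bridge_nodes(bt, cfg["percentile"])

    # -- robustness --------------------------------------------------------
    if cfg["bootstrap"]["enabled"]:
        def _boot():
            boot = res.bootstrap_edges(
                B=cfg["bootstrap"]["B"], seed=seeds["edge_bootstrap"]
            )
            R = bei_replicates(boot, net.community_of_node)
            edge_diff = _rob.difference_tests(boot)
            bei_diff = _rob.difference_tests(R, labels=list(net.labels))
            return boot, edge_diff, bei_diff

        boot, edge_diff, bei_diff = _run("edge_bootstrap", _boot)
        payload["edge_bootstrap"] = {
            "B": boot.B,
            "n_failed": boot.n_failed,
            "seed": boot.seed,
            "ci": {
                f"{a}--{b}": [float(lo), float(hi)]
                for (a, b), lo, hi in zip(boot.pairs, boot.ci_lower, boot.ci_upper)
            },
        }
        payload["difference_tests"] = {
            "alpha": 0.05,
            "note": "percentile bootstrap CIs of pairwise differences, "
            "no multiplicity correction",
            "edge_pairs_different": int(edge_diff.to_numpy().sum() // 2),
            "bei_pairs_different": int(bei_diff.to_numpy().sum() // 2),
            "bei_flags": {
                f"{a}--{b}": True
                for a in bei_diff.index
                for b in bei_diff.columns
                if a < b and bool(bei_diff.loc[a, b])
            },
        }

    if cfg["case_drop"]["enabled"]:
        def _cs():
            cd = res.case_drop(
                grid=cfg["case_drop"]["grid"],
                B=cfg["case_drop"]["B"],
                seed=seeds["case_drop"],
            )
            cs = _rob.cs_coefficient(
                cd,
                cor_threshold=cfg["case_drop"]["cor_threshold"],
                prob=cfg["case_drop"]["prob"],
            )
            return cd, cs

        cd, cs = _run("case_drop", _cs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_cor = np.nanmean(cd.correlations, axis=1)
        payload["case_drop"] = {
            "B": cfg["case_drop"]["B"],
            "seed": cd.seed,
            "proportions": [float(q) for q in cd.drop_proportions],
            "mean_correlation": [float(c) for c in mean_cor],
            "skipped": cd.skipped,
        }
        payload["cs_coefficient"] = {
            "value": cs.value,
            "cor_threshold": cs.cor_threshold,
            "prob_threshold": cs.prob_threshold,
        }

    # -- layout / export ---------------------------------------------------
    if cfg["layout"]["enabled"]:
        def _layout():
            return fruchterman_reingold(
                net, iterations=cfg["layout"]["iterations"], seed=seeds["layout"]
            )

        lay = _run("layout", _layout)
        payload["layout"] = {
            "seed": lay.seed,
            "iterations": lay.iterations,
            "coordinates": {
                l: [float(x), float(y)]
                for l, (x, y) in zip(lay.labels, lay.coordinates)
            },
        }
        if cfg.get("out_dir"):
            _run(
                "export",
                lambda: export_network(net, bt, lay, out_dir=cfg["out_dir"]),
            )

    payload["warnings"] = sorted(set(caught))
    report = AnalysisReport(payload=payload)
    if cfg.get("out_dir"):
        report.save(Path(cfg["out_dir"]) / "report.json")
    return report


def _all_edges(net):
    from .ggm import EDGE_EPS

    out = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = float(net.weights[i, j])
            if abs(w) > EDGE_EPS:
                out.append((net.labels[i], net.labels[j], w))
    out.sort(key=lambda e: abs(e[2]), reverse=True)
    return out
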