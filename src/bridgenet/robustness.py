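"""Bootstrap robustness checks for regularized symptom networks.

Three procedures, all exactly reproducible given (data, B, seed):

* nonparametric bootstrap of edge weights with percentile 95% CIs,
* case-dropping bootstrap of bridge expected influence with the
  correlation-stability (CS) coefficient,
* bootstrapped difference tests for edges or node statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bridge import bridge_expected_influence
from .ggm import estimate_network
from .scoring import NodeScoreTable

__all__ = [
    "EdgeBootstrapResult",
    "CaseDropResult",
    "CSCoefficient",
    "bootstrap_edge_ci",
    "case_drop_bootstrap",
    "cs_coefficient",
    "difference_tests",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


def _scores_frame(scores):
    if isinstance(scores, NodeScoreTable):
        return scores.scores, dict(scores.community_of_node)
    return pd.DataFrame(scores), {}


@dataclass
class EdgeBootstrapResult:
    """Edge-weight bootstrap replicates and percentile CIs.

    ``replicates`` has one row per successful replicate and one column per
    node pair (upper triangle, ``pairs`` order).
    """

    pairs: list  # (label_a, label_b)
    sample: np.ndarray  # full-sample edge weights
    replicates: np.ndarray  # B_ok x m
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    n_failed: int = 0
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.pairs, names=["node_a", "node_b"])
        return pd.DataFrame(
            {
                "sample": self.sample,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "boot_mean": self.replicates.mean(axis=0),
            },
            index=idx,
        )


@dataclass
class CaseDropResult:
    """Correlations between subsample and full-sample statistic vectors.

    ``correlations[k]`` holds the B replicate correlations at drop
    proportion ``drop_proportions[k]``; undefined correlations (constant
    statistic vector) are stored as NaN.
    """

    drop_proportions: np.ndarray
    correlations: np.ndarray  # len(grid) x B
    statistic: str = "bei"
    full_sample: np.ndarray | None = None
    skipped: list = field(default_factory=list)
    seed: int | None = None


@dataclass
class CSCoefficient:
    """Correlation-stability coefficient.

    The largest drop proportion q such that at every proportion q' <= q at
    least ``prob_threshold`` of replicate correlations reach
    ``cor_threshold``; by convention >0.5 is read as ideal stability and
    >0.25 as acceptable.
    """

    value: float
    cor_threshold: float = 0.7
    prob_threshold: float = 0.95


def _upper_pairs(labels):
    p = len(labels)
    return [(labels[i], labels[j]) for i in range(p) for j in range(i + 1, p)]


def bootstrap_edge_ci(
    scores, B=1000, gamma=0.5, seed=None, ci_level=0.95, **fit_kwargs
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of all edge weights with percentile CIs.

    Each replicate resamples the n respondents with replacement and re-runs
    the full estimation (correlation -> penalty path -> EBIC selection).
    Replicates where estimation fails are dropped and counted; more than 5%
    failures aborts.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrapping")
    df, comm = _scores_frame(scores)
    n = len(df)
    rng = np.random.default_rng(seed)
    full = estimate_network(df, comm, gamma=gamma, keep_path=False, **fit_kwargs)
    iu = np.triu_indices(full.p, k=1)
    sample_w = full.weights[iu]
    reps, failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            net = estimate_network(
                df.iloc[idx], comm, gamma=gamma, keep_path=False, **fit_kwargs
            )
            reps.append(net.weights[iu])
        except Exception:
            failed += 1
            if failed > 0.05 * B:
                raise RuntimeError(
                    f"more than 5% of bootstrap replicates failed ({failed}/{B})"
                )
    R = np.vstack(reps)
    a = 100.0 * (1.0 - ci_level) / 2.0
    lo = np.percentile(R, a, axis=0)
    hi = np.percentile(R, 100.0 - a, axis=0)
    return EdgeBootstrapResult(
        pairs=_upper_pairs(full.labels),
        sample=sample_w,
        replicates=R,
        ci_lower=lo,
        ci_upper=hi,
        B=B,
        n_failed=failed,
        seed=seed,
    )


def _vector_corr(a, b, method="pearson"):
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    scores,
    grid=DEFAULT_DROP_GRID,
    B=1000,
    gamma=0.5,
    seed=None,
    correlation="pearson",
    **fit_kwargs,
) -> CaseDropResult:
    """Case-dropping bootstrap of bridge expected influence.

    For each drop proportion q, each replicate removes ``floor(q n)``
    distinct respondents uniformly at random, re-estimates the network,
    recomputes BEI, and records its correlation with the full-sample BEI
    vector.  Proportions leaving fewer than p+1 respondents are skipped
    with a warning.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if seed is None:
        raise ValueError("seed is required for reproducible bootstrapping")
    grid = np.asarray(sorted(float(q) for q in grid))
    if grid.size == 0 or grid.min() <= 0 or grid.max() >= 0.95:
        raise ValueError("drop proportions must lie in (0, 0.95)")
    df, comm = _scores_frame(scores)
    n, p = df.shape
    rng = np.random.default_rng(seed)
    full = estimate_network(df, comm, gamma=gamma, keep_path=False, **fit_kwargs)
    full_bei = bridge_expected_influence(full).bei
    if np.std(full_bei) == 0:
        warnings.warn(
            "full-sample BEI vector is constant; stability correlations are "
            "undefined",
            UserWarning,
            stacklevel=2,
        )
    kept, rows, skipped = [], [], []
    warned_nan = False
    for q in grid:
        keep = n - int(np.floor(q * n))
        if keep < p + 1:
            warnings.warn(
                f"drop proportion {q:g} leaves {keep} < p+1 respondents; skipped",
                UserWarning,
                stacklevel=2,
            )
            skipped.append(float(q))
            continue
        row = np.empty(B)
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            net = estimate_network(
                df.iloc[idx], comm, gamma=gamma, keep_path=False, **fit_kwargs
            )
            bei = bridge_expected_influence(net).bei
            r = _vector_corr(bei, full_bei, method=correlation)
            if np.isnan(r) and not warned_nan:
                warnings.warn(
                    "constant statistic vector in a replicate; correlation "
                    "recorded as missing",
                    UserWarning,
                    stacklevel=2,
                )
                warned_nan = True
            row[b] = r
        kept.append(float(q))
        rows.append(row)
    return CaseDropResult(
        drop_proportions=np.asarray(kept),
        correlations=np.vstack(rows) if rows else np.empty((0, B)),
        statistic="bei",
        full_sample=full_bei,
        skipped=skipped,
        seed=seed,
    )


def cs_coefficient(result: CaseDropResult, cor_threshold=0.7, prob=0.95) -> CSCoefficient:
    """CS-coefficient of a case-dropping bootstrap.

    The largest grid proportion q such that for every grid proportion
    q' <= q, at least ``prob`` of the (defined) replicate correlations at q'
    are >= ``cor_threshold``; 0 if the condition fails already at the
    smallest proportion.  NaN correlations are excluded.
    """
    if result.drop_proportions.size == 0:
        raise ValueError("empty case-dropping result")
    value = 0.0
    for q, row in zip(result.drop_proportions, result.correlations):
        ok = row[~np.isnan(row)]
        if ok.size == 0 or np.mean(ok >= cor_threshold) < prob:
            break
        value = float(q)
    return CSCoefficient(value=value, cor_threshold=cor_threshold, prob_threshold=prob)


def difference_tests(replicates, labels=None, alpha=0.05) -> pd.DataFrame:
    """Bootstrapped difference test over a replicate matrix.

    ``replicates`` is B x m (edge weights or node statistics per replicate).
    For each pair of columns the percentile ``1-alpha`` CI of the replicate
    differences is formed; the pair is flagged different iff the CI excludes
    zero.  Returns a symmetric boolean DataFrame with a False diagonal.
    No multiplicity correction is applied; treat many simultaneous flags
    descriptively.
    """
    if isinstance(replicates, EdgeBootstrapResult):
        labels = [f"{a}--{b}" for a, b in replicates.pairs]
        R = replicates.replicates
    else:
        R = np.asarray(replicates, dtype=float)
    if R.ndim != 2:
        raise ValueError("replicates must be a B x m matrix")
    m = R.shape[1]
    if labels is None:
        labels = list(range(m))
    lo_q, hi_q = 100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0)
    flags = np.zeros((m, m), dtype=bool)
    for i in range(m):
        d = R[:, i : i + 1] - R[:, i + 1 :]
        if d.shape[1] == 0:
            continue
        lo = np.percentile(d, lo_q, axis=0)
        hi = np.percentile(d, hi_q, axis=0)
        sig = (lo > 0) | (hi < 0)
        flags[i, i + 1 :] = sig
        flags[i + 1 :, i] = sig
    return pd.DataFrame(flags, index=labels, columns=labels)
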