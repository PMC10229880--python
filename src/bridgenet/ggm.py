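"""Regularized Gaussian graphical model estimation.

Pipeline: marginal correlations -> graphical-lasso path -> EBIC model
selection -> partial-correlation edge weights.  The L1 penalty is applied
to off-diagonal precision entries only; EBIC with hyperparameter gamma
(default 0.5) trades sensitivity against specificity, and ties are broken
toward the sparser model.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "CorrelationMatrix",
    "PrecisionMatrix",
    "LambdaPath",
    "PartialCorrelationNetwork",
    "GlassoConvergenceError",
    "GlassoConvergenceWarning",
    "sample_correlation",
    "lambda_path_grid",
    "glasso_fit",
    "gaussian_loglik",
    "ebic_score",
    "precision_to_pcor",
    "estimate_network",
]

#: precision entries below this magnitude count as structural zeros
EDGE_EPS = 1e-10


class GlassoConvergenceError(RuntimeError):
    """Graphical-lasso solver failed; carries the penalty level."""

    def __init__(self, lam, cause):
        super().__init__(f"graphical lasso failed at lambda={lam:.6g}: {cause}")
        self.lam = lam


class GlassoConvergenceWarning(UserWarning):
    """Solver stopped at the iteration cap without meeting the gap tolerance."""


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray
    method: str = "pearson"
    repaired: bool = False

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.shape[0] != V.shape[1] or not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("correlation matrix must be square and symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = (V + V.T) / 2.0
        np.fill_diagonal(self.values, 1.0)

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class PrecisionMatrix:
    values: np.ndarray
    lam: float
    n_iter: int = 0

    @property
    def edge_count(self) -> int:
        """Number of nonzero off-diagonal pairs."""
        K = self.values
        iu = np.triu_indices_from(K, k=1)
        return int(np.sum(np.abs(K[iu]) > EDGE_EPS))


@dataclass
class LambdaPath:
    lambdas: np.ndarray
    fits: list
    ebic_scores: np.ndarray
    gamma: float

    @property
    def selected_index(self) -> int:
        # np.argmin returns the first minimiser; lambdas are decreasing, so
        # ties resolve to the larger penalty (sparser model)
        return int(np.argmin(self.ebic_scores))


@dataclass
class PartialCorrelationNetwork:
    """A regularized partial-correlation network over labelled nodes.

    ``weights`` is symmetric with an exactly zero diagonal; its sparsity
    pattern equals that of the selected precision matrix.
    """

    labels: list
    weights: np.ndarray
    community_of_node: dict
    n: int
    selected_lambda: float = np.nan
    gamma: float = np.nan
    correlation_method: str = "pearson"
    path: LambdaPath | None = None

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(W[~np.eye(len(W), dtype=bool)]).max(initial=0.0) >= 1.0:
            raise ValueError("partial correlations must lie strictly in (-1, 1)")
        self.weights = (W + W.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.sum(np.abs(self.weights[iu]) > EDGE_EPS))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)


def sample_correlation(scores, method="pearson") -> CorrelationMatrix:
    """Marginal correlation matrix of the node scores.

    Constant columns are rejected by name.  If the matrix is not positive
    definite (possible with Spearman or after heavy discretization) it is
    repaired by clipping eigenvalues at 1e-8 and renormalising to unit
    diagonal, with a warning.
    """
    from .scoring import NodeScoreTable

    df = scores.scores if isinstance(scores, NodeScoreTable) else pd.DataFrame(scores)
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method: {method!r}")
    sd = df.std(axis=0, ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant node column(s): {constant}")
    V = df.corr(method=method).to_numpy()
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 1.0)
    repaired = False
    w = np.linalg.eigvalsh(V)
    if w.min() <= 0:
        warnings.warn(
            "sample correlation matrix not positive definite; "
            "repaired by eigenvalue clipping",
            UserWarning,
            stacklevel=2,
        )
        eva, eve = np.linalg.eigh(V)
        eva = np.clip(eva, 1e-8, None)
        V = eve @ np.diag(eva) @ eve.T
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 1.0)
        repaired = True
    return CorrelationMatrix(
        labels=list(df.columns), values=V, method=method, repaired=repaired
    )


def lambda_path_grid(S, n_lambda=100, min_ratio=0.01) -> np.ndarray:
    """Logarithmically spaced decreasing penalty grid.

    The first grid point is ``max |off-diagonal of S|`` (the smallest
    penalty yielding the empty graph); the last is ``min_ratio`` times that.
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must lie in (0, 1)")
    V = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    off = V[~np.eye(V.shape[0], dtype=bool)]
    lam_max = float(np.abs(off).max(initial=0.0))
    if lam_max == 0.0:
        warnings.warn(
            "all off-diagonal correlations are zero; degenerate single-point "
            "path at lambda=0",
            UserWarning,
            stacklevel=2,
        )
        return np.array([0.0])
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def glasso_fit(S, lam, tol=1e-4, max_iter=1000) -> PrecisionMatrix:
    """Graphical lasso at a single penalty level.

    Maximises ``log det K - tr(S K) - lam * sum_{i!=j} |K_ij|`` (diagonal
    unpenalized).  ``lam=0`` is the unregularized Gaussian MLE, ``K = S^-1``.
    """
    V = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            _, K, n_iter = _sk_glasso(
                V, alpha=float(lam), tol=tol, max_iter=max_iter, return_n_iter=True
            )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                # tolerate a terminal gap within one order of the tolerance
                # (the solver's gap estimate has a numerical floor); warn on
                # anything genuinely unconverged
                m = re.search(r"dual gap: (-?[\d.e+-]+)", str(w.message))
                gap = abs(float(m.group(1))) if m else np.inf
                if gap > 10 * tol:
                    warnings.warn(
                        f"graphical lasso hit the iteration cap ({max_iter}) "
                        f"at lambda={lam:.6g} with dual gap {gap:.3g}",
                        GlassoConvergenceWarning,
                        stacklevel=2,
                    )
    except (FloatingPointError, np.linalg.LinAlgError) as exc:
        raise GlassoConvergenceError(lam, exc) from exc
    K = (K + K.T) / 2.0
    return PrecisionMatrix(values=K, lam=float(lam), n_iter=int(n_iter))


def gaussian_loglik(K, S, n) -> float:
    """Profile Gaussian log-likelihood ``(n/2) (log det K - tr(S K))``."""
    Kv = K.values if isinstance(K, PrecisionMatrix) else np.asarray(K, dtype=float)
    Sv = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, dtype=float)
    sign, logdet = np.linalg.slogdet(Kv)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    return float(n / 2.0 * (logdet - np.trace(Sv @ Kv)))


def ebic_score(K, S, n, gamma=0.5) -> float:
    """Extended BIC: ``-2 L + E log n + 4 gamma E log p`` with ``E`` the
    number of nonzero off-diagonal pairs.  ``gamma=0`` reduces to BIC."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    Kp = K if isinstance(K, PrecisionMatrix) else PrecisionMatrix(np.asarray(K), 0.0)
    p = Kp.values.shape[0]
    E = Kp.edge_count
    L = gaussian_loglik(Kp, S, n)
    return float(-2.0 * L + E * np.log(n) + 4.0 * gamma * E * np.log(p))


def precision_to_pcor(K) -> np.ndarray:
    """Partial correlations from a precision matrix:
    ``rho_ij = -K_ij / sqrt(K_ii K_jj)``, zero diagonal."""
    Kv = K.values if isinstance(K, PrecisionMatrix) else np.asarray(K, dtype=float)
    d = np.diag(Kv)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    P = -Kv / np.sqrt(np.outer(d, d))
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    # exact zeros in K stay exact zeros in the network
    P[np.abs(Kv) <= EDGE_EPS] = 0.0
    np.fill_diagonal(P, 0.0)
    return P


def estimate_network(
    scores,
    community_of_node=None,
    gamma=0.5,
    method="pearson",
    n_lambda=100,
    lambda_min_ratio=0.01,
    tol=1e-4,
    max_iter=1000,
    keep_path=True,
) -> PartialCorrelationNetwork:
    """Estimate the EBIC-selected regularized partial-correlation network.

    Fits the full decreasing penalty path, scores each fit by EBIC and keeps
    the minimiser (ties toward the sparser model), then converts the selected
    precision matrix to partial correlations.
    """
    from .scoring import NodeScoreTable

    if isinstance(scores, NodeScoreTable):
        df = scores.scores
        if community_of_node is None:
            community_of_node = dict(scores.community_of_node)
    else:
        df = pd.DataFrame(scores)
    if community_of_node is None:
        community_of_node = {}
    n = len(df)
    S = sample_correlation(df, method=method)
    lambdas = lambda_path_grid(S, n_lambda=n_lambda, min_ratio=lambda_min_ratio)
    fits, scores_ = [], []
    for lam in lambdas:
        K = glasso_fit(S, lam, tol=tol, max_iter=max_iter)
        fits.append(K)
        scores_.append(ebic_score(K, S, n, gamma=gamma))
    path = LambdaPath(
        lambdas=np.asarray(lambdas),
        fits=fits,
        ebic_scores=np.asarray(scores_),
        gamma=gamma,
    )
    best = path.selected_index
    W = precision_to_pcor(fits[best])
    return PartialCorrelationNetwork(
        labels=list(df.columns),
        weights=W,
        community_of_node=community_of_node,
        n=n,
        selected_lambda=float(lambdas[best]),
        gamma=gamma,
        correlation_method=method,
        path=path if keep_path else None,
    )
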