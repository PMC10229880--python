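"""Graphical-lasso network estimation: solver wrapper, EBIC, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bridgenet as bn
from bridgenet.ggm import (
    EDGE_EPS,
    CorrelationMatrix,
    ebic_score,
    estimate_network,
    gaussian_loglik,
    glasso_fit,
    lambda_path_grid,
    precision_to_pcor,
    sample_correlation,
)


def random_pd_precision(p, seed, sparsity=0.5):
    rng = np.random.default_rng(seed)
    K = np.eye(p)
    iu = np.triu_indices(p, 1)
    vals = rng.uniform(-0.4, 0.4, size=len(iu[0]))
    vals[rng.random(len(vals)) < sparsity] = 0.0
    K[iu] = vals
    K = np.triu(K) + np.triu(K, 1).T
    K += (0.1 - min(np.linalg.eigvalsh(K).min(), 0)) * np.eye(p)
    return K


class TestSampleCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=50)
        S = sample_correlation(pd.DataFrame({"a": x, "b": x, "c": -x}))
        assert S.values[0, 1] == pytest.approx(1.0)
        assert S.values[0, 2] == pytest.approx(-1.0)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"ok": [1, 2, 3], "flat": [5, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            sample_correlation(df)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10000, 5)), columns=list("abcde"))
        S = sample_correlation(df).values
        off = S[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_recovers_planted_latent_correlations(self, default_spec):
        cohort = bn.simulate_cohort(default_spec, 5000, seed=3, keep_latent=True)
        S = np.corrcoef(cohort.latent.T)
        emp = sample_correlation(pd.DataFrame(cohort.latent)).values
        assert np.abs(emp - S).max() < 1e-12  # same data, sanity
        assert np.abs(S - default_spec.sigma).max() < 0.05

    def test_spearman_supported_and_others_rejected(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        assert sample_correlation(df, method="spearman").method == "spearman"
        with pytest.raises(ValueError):
            sample_correlation(df, method="polychoric")


class TestLambdaPath:
    def test_first_point_is_max_off_diagonal(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.6
        S[1, 2] = S[2, 1] = -0.2
        grid = lambda_path_grid(CorrelationMatrix(list("abc"), S))
        assert grid[0] == pytest.approx(0.6)

    def test_grid_size_and_last_point(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        grid = lambda_path_grid(S, n_lambda=100, min_ratio=0.01)
        assert len(grid) == 100
        assert grid[-1] == pytest.approx(0.5 / 100)

    @given(st.floats(0.05, 0.95), st.integers(2, 50))
    def test_grid_strictly_decreasing(self, rmax, n_lambda):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = rmax
        grid = lambda_path_grid(S, n_lambda=n_lambda)
        assert np.all(np.diff(grid) < 0)

    def test_zero_matrix_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            grid = lambda_path_grid(np.eye(4))
        assert list(grid) == [0.0]


class TestGlassoFit:
    def test_identity_input_gives_identity_precision(self):
        for lam in (0.0, 0.1, 1.0):
            K = glasso_fit(np.eye(5), lam).values
            assert np.allclose(K, np.eye(5), atol=1e-8)

    def test_unpenalized_fit_equals_direct_inversion(self):
        K0 = random_pd_precision(3, seed=4, sparsity=0.0)
        S = np.linalg.inv(K0)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        K = glasso_fit(S, 0.0).values
        assert np.abs(K - np.linalg.inv(S)).max() < 1e-6

    def test_penalty_at_or_above_lambda_max_empties_graph(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 6))
        X[:, 1] += 0.5 * X[:, 0]
        S = np.corrcoef(X.T)
        lam_max = np.abs(S - np.eye(6)).max()
        for lam in (lam_max, 1.5 * lam_max):
            K = glasso_fit(S, lam).values
            off = K[~np.eye(6, dtype=bool)]
            assert np.abs(off).max() < 1e-10

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(3), -0.1)


class TestLoglikAndEbic:
    def test_identity_closed_form(self):
        # K = S = I, p=2, n=10: L = 5 * (0 - 2) = -10
        assert gaussian_loglik(np.eye(2), np.eye(2), 10) == pytest.approx(-10.0)

    def test_loglik_maximized_at_inverse(self):
        K0 = random_pd_precision(3, seed=6, sparsity=0.0)
        S = np.linalg.inv(K0)
        best = gaussian_loglik(np.linalg.inv(S), S, 50)
        rng = np.random.default_rng(7)
        for _ in range(20):
            P = random_pd_precision(3, seed=rng.integers(1 << 30))
            assert gaussian_loglik(P, S, 50) <= best + 1e-9

    def test_loglik_scales_linearly_in_n(self):
        K = random_pd_precision(4, seed=8)
        S = np.linalg.inv(random_pd_precision(4, seed=9, sparsity=0.0))
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        assert gaussian_loglik(K, S, 200) == pytest.approx(
            2 * gaussian_loglik(K, S, 100)
        )

    def test_non_pd_precision_rejected(self):
        K = np.diag([1.0, -1.0])
        with pytest.raises(ValueError):
            gaussian_loglik(K, np.eye(2), 10)

    @given(st.integers(0, 1 << 20))
    def test_gamma_zero_reduces_to_bic(self, seed):
        K = random_pd_precision(4, seed=seed)
        S = np.linalg.inv(random_pd_precision(4, seed=seed + 1, sparsity=0.0))
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        E = np.sum(np.abs(K[np.triu_indices(4, 1)]) > EDGE_EPS)
        L = gaussian_loglik(K, S, 120)
        assert ebic_score(K, S, 120, gamma=0.0) == pytest.approx(
            -2 * L + E * np.log(120)
        )

    def test_empty_graph_penalty_free(self):
        K = np.diag([1.0, 2.0, 0.5])
        S = np.eye(3)
        L = gaussian_loglik(K, S, 80)
        for g in (0.0, 0.5, 2.0):
            assert ebic_score(K, S, 80, gamma=g) == pytest.approx(-2 * L)

    def test_penalty_term_hand_arithmetic(self):
        # 3 nodes, 2 edges, n=100, gamma=0.5
        K = np.eye(3)
        K[0, 1] = K[1, 0] = -0.2
        K[1, 2] = K[2, 1] = -0.1
        S = np.eye(3)
        L = gaussian_loglik(K, S, 100)
        expected_penalty = 2 * np.log(100) + 4 * 0.5 * 2 * np.log(3)
        assert ebic_score(K, S, 100, gamma=0.5) == pytest.approx(
            -2 * L + expected_penalty
        )


class TestPrecisionToPcor:
    def test_diagonal_precision_gives_empty_network(self):
        P = precision_to_pcor(np.diag([2.0, 3.0, 0.5]))
        assert np.all(P == 0)

    def test_two_by_two_formula(self):
        K = np.array([[1.0, -0.3], [-0.3, 1.0]])
        P = precision_to_pcor(K)
        assert P[0, 1] == pytest.approx(0.3)

    def test_matches_schur_complement_oracle(self):
        # partial corr of (i, j) given the rest from the Schur complement of
        # the covariance — an independent route to the same quantity
        for seed in range(5):
            K = random_pd_precision(4, seed=100 + seed, sparsity=0.0)
            Sig = np.linalg.inv(K)
            P = precision_to_pcor(K)
            for i in range(4):
                for j in range(i + 1, 4):
                    rest = [k for k in range(4) if k not in (i, j)]
                    A = Sig[np.ix_([i, j], [i, j])]
                    B = Sig[np.ix_([i, j], rest)]
                    D = Sig[np.ix_(rest, rest)]
                    C = A - B @ np.linalg.solve(D, B.T)
                    oracle = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
                    assert abs(P[i, j] - oracle) < 1e-8


class TestEstimateNetwork:
    def test_independent_data_yields_empty_network(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(5000, 6)), columns=list("abcdef"))
        net = estimate_network(df)
        assert net.edge_count == 0

    def test_edge_count_monotone_along_path(self, net2000):
        counts = [f.edge_count for f in net2000.path.fits]
        # lambdas decrease along the path, so counts must not decrease
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_weights_shape_and_bounds(self, net2000):
        W = net2000.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.abs(W).max() < 1.0
        assert net2000.edge_count <= 14 * 13 // 2

    def test_selection_prefers_sparser_on_ties(self):
        # identical EBIC scores arise for identical fits; first (largest
        # lambda) index must win
        from bridgenet.ggm import LambdaPath, PrecisionMatrix

        fits = [PrecisionMatrix(np.eye(2), 0.5), PrecisionMatrix(np.eye(2), 0.1)]
        path = LambdaPath(np.array([0.5, 0.1]), fits, np.array([3.0, 3.0]), 0.5)
        assert path.selected_index == 0

    def test_unregularized_limit_matches_inversion(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(400, 4))
        X[:, 2] += 0.6 * X[:, 0]
        df = pd.DataFrame(X, columns=list("abcd"))
        S = sample_correlation(df)
        net_zero = precision_to_pcor(glasso_fit(S, 0.0).values)
        oracle = precision_to_pcor(np.linalg.inv(S.values))
        assert np.abs(net_zero - oracle).max() < 1e-6

    def test_sparsity_pattern_equivariant_to_node_order(self):
        rng = np.random.default_rng(14)
        K = random_pd_precision(6, seed=15, sparsity=0.6)
        Sig = np.linalg.inv(K)
        d = np.sqrt(np.diag(Sig))
        Sig = Sig / np.outer(d, d)
        X = rng.multivariate_normal(np.zeros(6), Sig, size=800)
        cols = list("abcdef")
        df = pd.DataFrame(X, columns=cols)
        net = estimate_network(df, keep_path=False)
        perm = [3, 0, 5, 1, 4, 2]
        dfp = df[[cols[i] for i in perm]]
        netp = estimate_network(dfp, keep_path=False)
        Wp_back = pd.DataFrame(
            netp.weights, index=netp.labels, columns=netp.labels
        ).loc[cols, cols]
        assert np.array_equal(
            np.abs(net.weights) > EDGE_EPS, np.abs(Wp_back.to_numpy()) > EDGE_EPS
        )
        # weights agree to solver tolerance (cd sweep order follows node order)
        assert np.abs(net.weights - Wp_back.to_numpy()).max() < 1e-3

    def test_pattern_matches_selected_precision(self, net2000):
        K = net2000.path.fits[net2000.path.selected_index].values
        assert np.array_equal(
            np.abs(net2000.weights) > EDGE_EPS, np.abs(K) > EDGE_EPS
        ) or np.array_equal(
            (np.abs(net2000.weights) > EDGE_EPS),
            (np.abs(K) > EDGE_EPS) & ~np.eye(14, dtype=bool),
        )
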