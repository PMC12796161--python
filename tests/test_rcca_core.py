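"""Solver correctness against independent oracles, and loading identities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import eigh as generalized_eigh

from modecca.rcca_core import (
    compute_loadings,
    fit_rcca,
    project_variates,
    redundancy_index,
)


def eigen_oracle(X, Y, cx, cy, n_modes):
    """Brute-force rCCA by the symmetric generalized eigenproblem

        [[0, Sxy], [Syx, 0]] z = s * blockdiag(Rx, Ry) z,

    solved with scipy's generalized eigensolver — an independent route to
    the same stationarity conditions the SVD solver optimizes.
    """
    n, p = X.shape
    q = Y.shape[1]
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    A = np.zeros((p + q, p + q))
    A[:p, p:] = Sxy
    A[p:, :p] = Sxy.T
    B = np.zeros((p + q, p + q))
    B[:p, :p] = (1 - cx) * Sxx + cx * np.eye(p)
    B[p:, p:] = (1 - cy) * Syy + cy * np.eye(q)
    evals, evecs = generalized_eigh(A, B)
    order = np.argsort(evals)[::-1][:n_modes]
    svals = evals[order]
    Wx = evecs[:p, order] * np.sqrt(2)  # z'Bz = 1 puts half the norm per side
    Wy = evecs[p:, order] * np.sqrt(2)
    for k in range(n_modes):
        j = int(np.argmax(np.abs(Wy[:, k])))
        if Wy[j, k] < 0:
            Wx[:, k] *= -1
            Wy[:, k] *= -1
    return Wx, Wy, svals


GRID = [(0.0, 0.0), (0.0, 0.5), (0.5, 0.0), (0.5, 0.5), (0.9, 0.3), (1.0, 1.0)]


class TestSolverOracle:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("cx,cy", GRID)
    def test_matches_generalized_eigenproblem(self, seed, cx, cy):
        rng = np.random.default_rng(seed)
        n, p, q = 60, 4, 3
        X = rng.normal(size=(n, p))
        Y = 0.4 * X[:, :q] + rng.normal(size=(n, q))
        m = fit_rcca(X, Y, cx, cy, n_modes=3)
        Wx, Wy, svals = eigen_oracle(X, Y, cx, cy, 3)
        np.testing.assert_allclose(m.wx, Wx, atol=1e-8)
        np.testing.assert_allclose(m.wy, Wy, atol=1e-8)
        if cx == 0 and cy == 0:
            # at the CCA limit the singular values are the training
            # correlations themselves
            np.testing.assert_allclose(m.train_correlations, svals, atol=1e-8)

    def test_pls_limit_is_cross_covariance_svd(self, rng):
        n, p, q = 80, 5, 4
        X = rng.normal(size=(n, p))
        Y = 0.5 * X[:, :q] + rng.normal(size=(n, q))
        m = fit_rcca(X, Y, 1.0, 1.0, n_modes=2)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        U, _, Vt = np.linalg.svd(Xc.T @ Yc / (n - 1))
        for k in range(2):
            u, v = U[:, k], Vt[k]
            if v[np.argmax(np.abs(v))] < 0:
                u, v = -u, -v
            np.testing.assert_allclose(m.wx[:, k], u, atol=1e-8)
            np.testing.assert_allclose(m.wy[:, k], v, atol=1e-8)

    def test_identical_matrices_correlate_perfectly(self, rng):
        X = rng.normal(size=(40, 3))
        m = fit_rcca(X, X.copy(), 0.0, 0.0, n_modes=1)
        assert m.train_correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_singular_covariance_requires_regularization(self, rng):
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0]])  # exactly collinear
        Y = rng.normal(size=(30, 2))
        with pytest.raises(np.linalg.LinAlgError, match="regularization"):
            fit_rcca(X, Y, 0.0, 0.0)
        fit_rcca(X, Y, 0.1, 0.0)  # small ridge suffices

    def test_scale_invariance_at_c0(self, rng):
        X = rng.normal(size=(50, 4))
        Y = 0.3 * X[:, :2] + rng.normal(size=(50, 2))
        r0 = fit_rcca(X, Y, 0.0, 0.0).train_correlations
        X2 = X * np.array([5.0, 0.1, 1.0, 3.0])
        r1 = fit_rcca(X2, Y, 0.0, 0.0).train_correlations
        np.testing.assert_allclose(r0, r1, atol=1e-10)

    def test_mode_orthogonality_under_regularized_metric(self, rng):
        X = rng.normal(size=(100, 5))
        Y = 0.4 * X[:, :4] + rng.normal(size=(100, 4))
        for c in (0.0, 0.5):
            m = fit_rcca(X, Y, c, c, n_modes=3)
            Xc = X - X.mean(0)
            Sxx = Xc.T @ Xc / 99
            Rx = (1 - c) * Sxx + c * np.eye(5)
            G = m.wx.T @ Rx @ m.wx
            np.testing.assert_allclose(G, np.eye(3), atol=1e-8)

    def test_train_correlations_non_increasing_at_c0(self, rng):
        X = rng.normal(size=(80, 5))
        Y = 0.5 * X[:, :4] + rng.normal(size=(80, 4))
        r = fit_rcca(X, Y, 0.0, 0.0, n_modes=4).train_correlations
        assert np.all(np.diff(r) <= 1e-12)

    def test_continuous_interpolation_cca_to_pls(self, rng):
        # weights must move smoothly along the regularization path
        X = rng.normal(size=(70, 4))
        Y = 0.5 * X[:, :3] + rng.normal(size=(70, 3))
        cs = np.linspace(0, 1, 41)
        ws = [fit_rcca(X, Y, c, c).wx[:, 0] for c in cs]
        steps = [np.linalg.norm(a - b) for a, b in zip(ws, ws[1:])]
        assert max(steps) < 0.15

    def test_sign_convention(self, rng):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3))
        m = fit_rcca(X, Y, 0.3, 0.3, n_modes=2)
        for k in range(2):
            j = np.argmax(np.abs(m.wy[:, k]))
            assert m.wy[j, k] > 0


class TestProjection:
    def test_training_projection_reproduces_training_correlations(self, rng):
        X = rng.normal(size=(60, 4))
        Y = 0.4 * X[:, :3] + rng.normal(size=(60, 3))
        m = fit_rcca(X, Y, 0.2, 0.6, n_modes=2)
        _, _, corrs = project_variates(m, X, Y)
        np.testing.assert_allclose(corrs, m.train_correlations, atol=1e-10)

    def test_noise_holdout_centers_on_zero(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            Xtr, Ytr = rng.normal(size=(50, 3)), rng.normal(size=(50, 2))
            m = fit_rcca(Xtr, Ytr, 0.0, 0.0)
            _, _, c = project_variates(m, rng.normal(size=(80, 3)), rng.normal(size=(80, 2)))
            rs.append(c[0])
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_rows_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 2))
        m = fit_rcca(X, Y, 0.0, 0.0)
        with pytest.raises(ValueError, match="3 subjects"):
            project_variates(m, X[:2], Y[:2])


class TestLoadings:
    def test_single_feature_loading_is_unit(self, rng):
        X = rng.normal(size=(50, 1))
        Y = 0.5 * X + rng.normal(size=(50, 2))
        m = fit_rcca(X, Y, 0.0, 0.0)
        tab = compute_loadings(m, X, Y)
        assert abs(tab.x_loadings.iloc[0, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_cross_loading_equals_loading_times_r_at_c0(self, rng):
        # exact stationarity identity of classical CCA:
        # cov(x_j, V) = r * cov(x_j, U)
        X = rng.normal(size=(80, 4))
        Y = 0.5 * X[:, :3] + rng.normal(size=(80, 3))
        m = fit_rcca(X, Y, 0.0, 0.0)
        tab = compute_loadings(m, X, Y)
        r = m.train_correlations[0]
        np.testing.assert_allclose(
            tab.x_cross_loadings["mode_1"],
            tab.x_loadings["mode_1"] * r,
            atol=1e-10,
        )

    def test_unloaded_feature_loading_vanishes_at_large_n(self):
        rng = np.random.default_rng(0)
        n = 20000
        z = rng.standard_normal(n)
        a = np.array([1.0, 1.0, 0.0])  # third feature carries no signal
        X = np.outer(z, a) + rng.standard_normal((n, 3))
        Y = np.outer(z, [1.0, 0.5]) + rng.standard_normal((n, 2))
        m = fit_rcca(X, Y, 0.0, 0.0)
        tab = compute_loadings(m, X, Y)
        assert abs(tab.x_loadings.iloc[2, 0]) < 0.03
        assert abs(tab.x_loadings.iloc[0, 0]) > 0.5

    def test_constant_feature_reported_missing(self, rng):
        X = np.column_stack([rng.normal(size=40), np.ones(40)])
        Y = rng.normal(size=(40, 2))
        m = fit_rcca(X, Y, 0.5, 0.5)
        tab = compute_loadings(m, X, Y)
        assert np.isnan(tab.x_loadings.iloc[1, 0])
        assert np.isfinite(tab.x_loadings.iloc[0, 0])


class TestRedundancyIndex:
    def test_quoted_arithmetic(self):
        assert redundancy_index([0.6, 0.8], 0.5) == pytest.approx(0.125)

    def test_zero_and_maximal_cases(self):
        assert redundancy_index([0.0, 0.0, 0.0], 0.9) == 0.0
        assert redundancy_index([1.0, -1.0], 1.0) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            redundancy_index([], 0.5)

    @given(
        st.lists(st.floats(-1, 1), min_size=1, max_size=20),
        st.floats(-1, 1),
    )
    def test_identity_against_direct_arithmetic(self, loadings, r):
        expected = sum(l**2 for l in loadings) / len(loadings) * r**2
        assert redundancy_index(loadings, r) == pytest.approx(expected, abs=1e-12)
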