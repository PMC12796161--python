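"""L2-regularized canonical correlation analysis.

Given standardized matrices ``X`` (n x p) and ``Y`` (n x q), the solver finds
weight vectors ``u``, ``v`` maximizing ``corr(Xu, Yv)`` subject to the
regularized normalizations ``u' R_x u = 1`` and ``v' R_y v = 1`` with

    R = (1 - c) * S + c * I,       c in [0, 1],

where ``S`` is the 1/(n-1)-normalized sample covariance.  ``c = 0`` is
classical CCA; ``c = 1`` replaces the covariance metric by the identity and
recovers partial least squares (the weights become the singular vectors of the
raw cross-covariance).  Intermediate ``c`` interpolates continuously, trading
correlation maximization against covariance maximization and stabilizing the
solution when features are collinear or outnumber subjects.

All modes are obtained at once from the singular value decomposition of the
doubly whitened cross-covariance ``R_x^{-1/2} S_xy R_y^{-1/2}``; the k-th
singular triplet maps back through the whitening transforms to the k-th pair
of weight vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .deconfound import DeconfounderState, apply_deconfounder

__all__ = [
    "RccaModel",
    "LoadingsTable",
    "fit_rcca",
    "project_variates",
    "compute_loadings",
    "redundancy_index",
]

_SINGULAR_TOL = 1e-10


def _check_c(c: float, name: str) -> float:
    c = float(c)
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {c}")
    return c


def _inv_sqrt_metric(S: np.ndarray, c: float, side: str) -> np.ndarray:
    """Inverse square root of the regularized metric (1-c) S + c I."""
    R = (1.0 - c) * S + c * np.eye(S.shape[0])
    evals, evecs = np.linalg.eigh(R)
    max_ev = float(evals.max(initial=0.0))
    if max_ev <= 0 or evals.min() <= _SINGULAR_TOL * max_ev:
        raise np.linalg.LinAlgError(
            f"{side}-side covariance metric is singular at c={c}; "
            "use a regularization parameter > 0"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


def rcca_weights_from_covs(
    Sxx: np.ndarray,
    Syy: np.ndarray,
    Sxy: np.ndarray,
    cx: float,
    cy: float,
    n_modes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weights and singular values from pre-computed covariance blocks.

    Returns ``(Wx, Wy, svals)`` with weights unit-length under their
    regularized metrics and signs fixed so the largest-magnitude Y-side
    weight entry of each mode is positive.
    """
    cx = _check_c(cx, "cx")
    cy = _check_c(cy, "cy")
    p, q = Sxy.shape
    if not (1 <= n_modes <= min(p, q)):
        raise ValueError(f"n_modes must be in [1, {min(p, q)}], got {n_modes}")
    Rx_inv = _inv_sqrt_metric(Sxx, cx, "X")
    Ry_inv = _inv_sqrt_metric(Syy, cy, "Y")
    K = Rx_inv @ Sxy @ Ry_inv
    U, svals, Vt = np.linalg.svd(K, full_matrices=False)
    Wx = Rx_inv @ U[:, :n_modes]
    Wy = Ry_inv @ Vt[:n_modes].T
    # renormalize exactly under the regularized metric (guards eigenvalue
    # clipping) and fix the sign convention
    Rx = (1.0 - cx) * Sxx + cx * np.eye(p)
    Ry = (1.0 - cy) * Syy + cy * np.eye(q)
    for k in range(n_modes):
        Wx[:, k] /= np.sqrt(Wx[:, k] @ Rx @ Wx[:, k])
        Wy[:, k] /= np.sqrt(Wy[:, k] @ Ry @ Wy[:, k])
        j = int(np.argmax(np.abs(Wy[:, k])))
        if Wy[j, k] < 0:
            Wx[:, k] *= -1.0
            Wy[:, k] *= -1.0
    return Wx, Wy, svals[:n_modes]


@dataclass
class RccaModel:
    """A fitted regularized CCA: weights, penalty pair and frozen transforms.

    ``train_correlations`` are the Pearson correlations of the training
    variates per mode.  The deconfounder states, when attached, let the model
    be applied directly to raw (confounded) matrices.
    """

    wx: np.ndarray
    wy: np.ndarray
    cx: float
    cy: float
    train_correlations: np.ndarray
    x_features: list[str]
    y_features: list[str]
    x_deconfounder: Optional[DeconfounderState] = None
    y_deconfounder: Optional[DeconfounderState] = None

    @property
    def n_modes(self) -> int:
        return self.wx.shape[1]


def _as_matrix(data, names_hint: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{names_hint}{j}" for j in range(arr.shape[1])]


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def fit_rcca(X, Y, cx: float, cy: float, n_modes: int = 1) -> RccaModel:
    """Fit a regularized CCA on standardized, deconfounded matrices."""
    Xa, x_names = _as_matrix(X, "x")
    Ya, y_names = _as_matrix(Y, "y")
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    n = Xa.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    Xc = Xa - Xa.mean(axis=0)
    Yc = Ya - Ya.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Wx, Wy, _ = rcca_weights_from_covs(Sxx, Syy, Sxy, cx, cy, n_modes)
    U = Xc @ Wx
    V = Yc @ Wy
    corrs = np.array([_pearson(U[:, k], V[:, k]) for k in range(n_modes)])
    return RccaModel(
        wx=Wx,
        wy=Wy,
        cx=float(cx),
        cy=float(cy),
        train_correlations=corrs,
        x_features=x_names,
        y_features=y_names,
    )


def _preprocess_side(model_state, data, confounds, names_hint):
    if model_state is not None:
        if confounds is None:
            raise ValueError("model carries a deconfounder; confounds are required")
        return apply_deconfounder(model_state, data, confounds).to_numpy()
    arr, _ = _as_matrix(data, names_hint)
    return arr


def project_variates(
    model: RccaModel, X, Y, x_confounds=None, y_confounds=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project (new) data onto the fitted weights.

    If the model carries deconfounder states they are applied (frozen) first.
    Returns ``(U, V, correlations)`` with one column / entry per mode; the
    per-mode correlation is the Pearson correlation of the paired variates.
    """
    Xt = _preprocess_side(model.x_deconfounder, X, x_confounds, "x")
    Yt = _preprocess_side(model.y_deconfounder, Y, y_confounds, "y")
    if Xt.shape[0] != Yt.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    if Xt.shape[0] < 3:
        raise ValueError("correlation undefined for fewer than 3 subjects")
    U = Xt @ model.wx
    V = Yt @ model.wy
    corrs = np.array([_pearson(U[:, k], V[:, k]) for k in range(model.n_modes)])
    return U, V, corrs


@dataclass
class LoadingsTable:
    """Structure correlations of input variables with the canonical variates.

    Every table is features x modes.  A *loading* correlates a variable with
    its own side's variate, a *cross-loading* with the opposite side's
    variate; both are plain Pearson correlations and live in [-1, 1].
    Constant features yield missing values.
    """

    x_loadings: pd.DataFrame
    x_cross_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    y_cross_loadings: pd.DataFrame


def _corr_with_variates(M: np.ndarray, variates: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations of M's features with each variate."""
    n = M.shape[0]
    Mc = M - M.mean(axis=0)
    Vc = variates - variates.mean(axis=0)
    m_sd = Mc.std(axis=0)
    v_sd = Vc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Mc.T @ Vc / n) / np.outer(m_sd, v_sd)
    out[m_sd == 0, :] = np.nan
    return out


def compute_loadings(
    model: RccaModel, X, Y, x_confounds=None, y_confounds=None
) -> LoadingsTable:
    """Loadings and cross-loadings of every variable, per mode."""
    Xt = _preprocess_side(model.x_deconfounder, X, x_confounds, "x")
    Yt = _preprocess_side(model.y_deconfounder, Y, y_confounds, "y")
    U = Xt @ model.wx
    V = Yt @ model.wy
    modes = [f"mode_{k + 1}" for k in range(model.n_modes)]
    x_feats = (
        model.x_deconfounder.feature_names if model.x_deconfounder else model.x_features
    )
    y_feats = (
        model.y_deconfounder.feature_names if model.y_deconfounder else model.y_features
    )
    if np.isnan(_corr_with_variates(Xt, U)).all() and Xt.shape[1]:
        warnings.warn("all X features constant; loadings undefined", stacklevel=2)
    return LoadingsTable(
        x_loadings=pd.DataFrame(_corr_with_variates(Xt, U), index=x_feats, columns=modes),
        x_cross_loadings=pd.DataFrame(
            _corr_with_variates(Xt, V), index=x_feats, columns=modes
        ),
        y_loadings=pd.DataFrame(_corr_with_variates(Yt, V), index=y_feats, columns=modes),
        y_cross_loadings=pd.DataFrame(
            _corr_with_variates(Yt, U), index=y_feats, columns=modes
        ),
    )


def redundancy_index(y_loadings, canonical_correlation: float) -> float:
    """Variance of Y explained through the X-side variate.

    The mean squared Y-side loading (shared variance between the Y variables
    and their variate) multiplied by the squared canonical correlation.
    """
    loadings = np.asarray(y_loadings, dtype=float).ravel()
    if loadings.size == 0:
        raise ValueError("empty loading vector")
    r = float(canonical_correlation)
    if not np.isfinite(r) or abs(r) > 1 + 1e-12:
        raise ValueError(f"canonical correlation must satisfy |r| <= 1, got {r}")
    return float(np.nanmean(loadings**2) * r**2)
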