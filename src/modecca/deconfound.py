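"""Cross-validation-consistent confound removal and standardization.

Nuisance variables (age, age squared, sex, total intracranial volume, cohort
indicators) are regressed out of every feature by ordinary least squares, and
the residuals are z-scored.  All parameters — regression coefficients,
confound centering means, residual means and SDs — are estimated on the
training rows only and then frozen, so that applying the transform to held-out
rows can never leak information from them back into the model.  Re-centering
or re-scaling on test rows is the classic leakage this design rules out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = ["DeconfounderState", "fit_deconfounder", "apply_deconfounder"]

_ZERO_VAR_TOL = 1e-12


@dataclass
class DeconfounderState:
    """Frozen parameters of a fitted deconfounder.

    ``coef`` has one row per retained confound column plus an intercept row
    (first), one column per retained feature.
    """

    confound_names: list[str]
    feature_names: list[str]
    dropped_features: list[str]
    dropped_confounds: list[str]
    coef: np.ndarray
    confound_means: np.ndarray
    residual_means: np.ndarray
    residual_sds: np.ndarray
    standardize: bool = True

    def to_yaml(self, path) -> None:
        payload = {
            "confound_names": self.confound_names,
            "feature_names": self.feature_names,
            "dropped_features": self.dropped_features,
            "dropped_confounds": self.dropped_confounds,
            "coef": self.coef.tolist(),
            "confound_means": self.confound_means.tolist(),
            "residual_means": self.residual_means.tolist(),
            "residual_sds": self.residual_sds.tolist(),
            "standardize": self.standardize,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DeconfounderState":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        for key in ("coef", "confound_means", "residual_means", "residual_sds"):
            payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


def _as_array(mat, names_hint: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(mat, pd.DataFrame):
        return mat.to_numpy(dtype=float), [str(c) for c in mat.columns]
    arr = np.asarray(mat, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{names_hint}{j}" for j in range(arr.shape[1])]


def _independent_columns(design: np.ndarray) -> list[int]:
    """Indices of a maximal linearly independent column subset (greedy)."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return keep


def fit_deconfounder(train_matrix, train_confounds, standardize: bool = True) -> DeconfounderState:
    """Fit confound-removal parameters on training rows only.

    Each feature is regressed on an intercept plus the mean-centered
    confounds.  Residual means and SDs are stored for the z-scoring step;
    features whose training residuals have (numerically) zero variance are
    dropped and recorded.  Linearly dependent confound columns are dropped
    with a warning.
    """
    X, feat_names = _as_array(train_matrix, "feature_")
    C, conf_names = _as_array(train_confounds, "confound_")
    if X.shape[0] != C.shape[0]:
        raise ValueError("train_matrix and train_confounds must have equal row counts")
    n = X.shape[0]
    if n <= C.shape[1] + 1:
        raise ValueError(
            f"need n_train > n_confounds + 1 (got n={n}, confounds={C.shape[1]})"
        )

    conf_means = C.mean(axis=0)
    Cc = C - conf_means
    keep = _independent_columns(Cc) if Cc.shape[1] else []
    dropped_conf = [conf_names[j] for j in range(Cc.shape[1]) if j not in keep]
    if dropped_conf:
        warnings.warn(
            f"dropping linearly dependent confound column(s): {dropped_conf}",
            stacklevel=2,
        )
    Cc = Cc[:, keep]
    conf_names = [conf_names[j] for j in keep]
    conf_means = conf_means[keep]

    design = np.column_stack([np.ones(n), Cc])
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ coef

    sds = resid.std(axis=0, ddof=1)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    zero_var = sds <= _ZERO_VAR_TOL * scale
    dropped_feat = [feat_names[j] for j in np.flatnonzero(zero_var)]
    if dropped_feat:
        warnings.warn(
            f"dropping zero-variance feature(s) after residualization: {dropped_feat}",
            stacklevel=2,
        )
    keep_feat = np.flatnonzero(~zero_var)

    return DeconfounderState(
        confound_names=conf_names,
        feature_names=[feat_names[j] for j in keep_feat],
        dropped_features=dropped_feat,
        dropped_confounds=dropped_conf,
        coef=coef[:, keep_feat],
        confound_means=conf_means,
        residual_means=resid[:, keep_feat].mean(axis=0),
        residual_sds=sds[keep_feat],
        standardize=standardize,
    )


def apply_deconfounder(state: DeconfounderState, matrix, confounds) -> pd.DataFrame:
    """Apply frozen deconfounding (and z-scoring) to any rows.

    The confounds are centered with the *training* means and the residuals
    standardized with the *training* statistics, so held-out rows are
    transformed independently of one another.
    """
    X, feat_names = _as_array(matrix, "feature_")
    C, conf_names = _as_array(confounds, "confound_")
    name_to_col = {name: j for j, name in enumerate(feat_names)}
    missing = [f for f in state.feature_names if f not in name_to_col]
    if missing:
        raise ValueError(f"matrix is missing fitted feature(s): {missing}")
    conf_to_col = {name: j for j, name in enumerate(conf_names)}
    missing_c = [c for c in state.confound_names if c not in conf_to_col]
    if missing_c:
        raise ValueError(f"confounds are missing fitted column(s): {missing_c}")

    Xs = X[:, [name_to_col[f] for f in state.feature_names]]
    Cs = C[:, [conf_to_col[c] for c in state.confound_names]]
    design = np.column_stack([np.ones(Xs.shape[0]), Cs - state.confound_means])
    resid = Xs - design @ state.coef
    if state.standardize:
        resid = (resid - state.residual_means) / state.residual_sds
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame(resid, index=index, columns=state.feature_names)
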