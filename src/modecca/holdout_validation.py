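"""Multiple-hold-out validation of regularized CCA models.

The machine-learning wrapper around the solver:

* the cohort is split into an 80% optimization set and a 20% hold-out set
  (outer split), keeping whole families on one side of every split;
* inside the optimization set, 50 inner 80/20 train/test splits score each
  candidate regularization pair by the *stability* of its weight vectors
  across refits and its mean test correlation; the pair closest (Euclidean
  distance, after min-max rescaling of both axes) to the ideal point of
  perfect stability and perfect correlation wins;
* the model is refit on the full optimization set with the winning pair and
  the hold-out subjects are projected onto its weights to estimate the
  hold-out canonical correlation;
* the outer split is repeated 100 times; reported correlations and loadings
  are averages over repeats (loadings after per-repeat sign alignment).

Deconfounding and standardization inside every repeat use only that repeat's
training rows (no leakage); ``deconfound_mode="all"`` deliberately fits them
on all rows instead and exists solely as an instrumented positive control for
leakage tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import AssembledData, ModelDefinition, assemble_model_matrices
from .deconfound import apply_deconfounder, fit_deconfounder
from .rcca_core import (
    RccaModel,
    compute_loadings,
    fit_rcca,
    rcca_weights_from_covs,
    redundancy_index,
)
from .synthetic_cohort import CohortBundle

__all__ = [
    "DEFAULT_GRID",
    "ValidationConfig",
    "HyperparamSearch",
    "ModeSummary",
    "make_block_splits",
    "weight_stability",
    "select_hyperparameters",
    "run_multiple_holdout",
]

#: default regularization grid: both CCA (0) and PLS (1) limits, denser near
#: the extremes where the interpolation moves fastest
_GRID_AXIS = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 1.0)
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (cx, cy) for cx in _GRID_AXIS for cy in _GRID_AXIS
)


@dataclass
class ValidationConfig:
    """Knobs of the multiple-hold-out framework (defaults = study design)."""

    n_outer: int = 100
    n_inner: int = 50
    outer_fraction: float = 0.2
    inner_fraction: float = 0.2
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    n_modes: int = 1
    seed: int = 0
    loadings_on: str = "optimization"  # or "holdout"
    deconfound_mode: str = "train"  # "all" = leaky positive control
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.outer_fraction < 1.0 and 0.0 < self.inner_fraction < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("repeat counts must be positive")
        if self.loadings_on not in ("optimization", "holdout"):
            raise ValueError("loadings_on must be 'optimization' or 'holdout'")
        if self.deconfound_mode not in ("train", "all"):
            raise ValueError("deconfound_mode must be 'train' or 'all'")
        if len(self.grid) == 0:
            raise ValueError("grid must be non-empty")


def make_block_splits(
    blocks: Sequence, fraction: float, n_repeats: int, seed
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Family-respecting random splits.

    Families are shuffled and assigned to the held-out side until its subject
    count first reaches ``fraction * n``; members of the same family never
    straddle a split.  Splits are drawn until distinct from previous ones
    (best effort, bounded retries), deterministically given ``seed``.
    """
    labels = np.asarray(blocks)
    n = labels.size
    if n == 0:
        raise ValueError("empty block labels")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 families to split")
    fam_members = [np.flatnonzero(codes == f) for f in range(uniq.size)]
    sizes = np.array([m.size for m in fam_members])
    target = fraction * n
    if sizes.max() > (1.0 - fraction) * n:
        warnings.warn(
            "a single family covers more than the in-side target; the split "
            "will be badly unbalanced",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    seen: set[frozenset] = set()
    for _ in range(n_repeats):
        for _attempt in range(50):
            order = rng.permutation(uniq.size)
            out_fams: list[int] = []
            count = 0
            for f in order:
                if count >= target:
                    break
                out_fams.append(f)
                count += sizes[f]
            key = frozenset(out_fams)
            if key not in seen:
                break
        seen.add(key)
        out_idx = np.sort(np.concatenate([fam_members[f] for f in out_fams]))
        mask = np.ones(n, dtype=bool)
        mask[out_idx] = False
        splits.append((np.flatnonzero(mask), out_idx))
    return splits


def weight_stability(weight_vectors: Sequence[np.ndarray]) -> float:
    """Mean absolute pairwise cosine similarity of weight vectors.

    Sign-invariant (a vector and its negation are perfectly similar); zero
    vectors are excluded with a warning.
    """
    vecs = [np.asarray(v, dtype=float).ravel() for v in weight_vectors]
    norms = [np.linalg.norm(v) for v in vecs]
    kept = [v / nv for v, nv in zip(vecs, norms) if nv > 0]
    if len(kept) < len(vecs):
        warnings.warn("excluding zero weight vector(s) from stability", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need at least 2 nonzero weight vectors")
    W = np.vstack(kept)
    G = np.abs(W @ W.T)
    iu = np.triu_indices(len(kept), k=1)
    return float(np.clip(G[iu].mean(), 0.0, 1.0))


@dataclass
class HyperparamSearch:
    """Inner-loop scores per candidate pair and the winning pair."""

    grid: list[tuple[float, float]]
    mean_test_correlation: np.ndarray
    stability: np.ndarray
    distance: np.ndarray
    selected: tuple[float, float]
    selected_index: int


def _rescale_axis(values: np.ndarray) -> np.ndarray:
    """Min-max rescale one criterion axis; a constant axis is uninformative
    and contributes zero distance (mapped to the ideal value 1)."""
    lo, hi = np.nanmin(values), np.nanmax(values)
    if not np.isfinite(lo) or hi - lo <= 1e-15:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def distance_to_ideal(stability: np.ndarray, mean_corr: np.ndarray) -> np.ndarray:
    """Euclidean distance to perfect (stability, correlation) after min-max
    rescaling of each axis across the grid."""
    s = _rescale_axis(np.asarray(stability, dtype=float))
    r = _rescale_axis(np.asarray(mean_corr, dtype=float))
    return np.hypot(1.0 - s, 1.0 - r)


def _select_from_scores(
    grid: list[tuple[float, float]], stability: np.ndarray, mean_corr: np.ndarray
) -> tuple[np.ndarray, int]:
    dist = distance_to_ideal(stability, mean_corr)
    finite = np.where(np.isfinite(dist), dist, np.inf)
    best = finite.min()
    if not np.isfinite(best):
        raise ValueError("all hyperparameter candidates degenerate")
    tied = np.flatnonzero(finite <= best + 1e-12)
    # ties broken toward the stronger penalty
    sel = int(tied[np.argmax([grid[i][0] + grid[i][1] for i in tied])])
    return dist, sel


def select_hyperparameters(
    X,
    Y,
    x_confounds,
    y_confounds,
    blocks,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    n_inner: int = 50,
    seed=0,
    inner_fraction: float = 0.2,
    standardize: bool = True,
    deconfound_mode: str = "train",
) -> HyperparamSearch:
    """Stability-distance selection of the regularization pair.

    Every candidate is refit on each of ``n_inner`` block-respecting inner
    train/test splits of the optimization set; its mean mode-1 test
    correlation and the stability of its weight vectors across refits are
    min-max rescaled across the grid, and the candidate closest to the ideal
    point (1, 1) wins.
    """
    grid = [tuple(map(float, g)) for g in grid]
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    Cx = np.asarray(x_confounds, dtype=float)
    Cy = np.asarray(y_confounds, dtype=float)
    splits = make_block_splits(blocks, inner_fraction, n_inner, seed)

    test_corrs = np.full((len(grid), len(splits)), np.nan)
    wx_store: list[list[np.ndarray]] = [[] for _ in grid]
    wy_store: list[list[np.ndarray]] = [[] for _ in grid]
    for s_idx, (tr, te) in enumerate(splits):
        fit_rows = np.arange(Xa.shape[0]) if deconfound_mode == "all" else tr
        sx = fit_deconfounder(Xa[fit_rows], Cx[fit_rows], standardize=standardize)
        sy = fit_deconfounder(Ya[fit_rows], Cy[fit_rows], standardize=standardize)
        Xtr = apply_deconfounder(sx, Xa[tr], Cx[tr]).to_numpy()
        Ytr = apply_deconfounder(sy, Ya[tr], Cy[tr]).to_numpy()
        Xte = apply_deconfounder(sx, Xa[te], Cx[te]).to_numpy()
        Yte = apply_deconfounder(sy, Ya[te], Cy[te]).to_numpy()
        Xtr_c = Xtr - Xtr.mean(axis=0)
        Ytr_c = Ytr - Ytr.mean(axis=0)
        m = len(tr)
        Sxx = Xtr_c.T @ Xtr_c / (m - 1)
        Syy = Ytr_c.T @ Ytr_c / (m - 1)
        Sxy = Xtr_c.T @ Ytr_c / (m - 1)
        for g_idx, (cx, cy) in enumerate(grid):
            try:
                wx, wy, _ = rcca_weights_from_covs(Sxx, Syy, Sxy, cx, cy, 1)
            except np.linalg.LinAlgError:
                continue
            u = Xte @ wx[:, 0]
            v = Yte @ wy[:, 0]
            if u.std() == 0 or v.std() == 0:
                continue
            test_corrs[g_idx, s_idx] = np.corrcoef(u, v)[0, 1]
            wx_store[g_idx].append(wx[:, 0])
            wy_store[g_idx].append(wy[:, 0])

    mean_corr = np.full(len(grid), np.nan)
    stability = np.full(len(grid), np.nan)
    for g_idx in range(len(grid)):
        vals = test_corrs[g_idx]
        if np.isfinite(vals).sum() == 0:
            continue
        mean_corr[g_idx] = np.nanmean(vals)
        if len(wx_store[g_idx]) >= 2:
            stability[g_idx] = 0.5 * (
                weight_stability(wx_store[g_idx]) + weight_stability(wy_store[g_idx])
            )
        else:
            stability[g_idx] = 1.0  # a single fit carries no instability signal
    dist, sel = _select_from_scores(grid, stability, mean_corr)
    return HyperparamSearch(
        grid=grid,
        mean_test_correlation=mean_corr,
        stability=stability,
        distance=dist,
        selected=grid[sel],
        selected_index=sel,
    )


@dataclass
class ModeSummary:
    """Aggregated results of the 100 outer repeats for one model."""

    label: str
    n_modes: int
    holdout_correlations: np.ndarray  # (n_success, n_modes)
    mean_holdout: np.ndarray
    sd_holdout: np.ndarray
    redundancy: np.ndarray  # (n_success, n_modes)
    mean_redundancy: np.ndarray
    selected_pairs: np.ndarray  # (n_success, 2)
    median_pair: tuple[float, float]
    x_loadings_mean: pd.DataFrame
    x_loadings_sd: pd.DataFrame
    y_loadings_mean: pd.DataFrame
    y_loadings_sd: pd.DataFrame
    x_cross_loadings_mean: pd.DataFrame
    y_cross_loadings_mean: pd.DataFrame
    outer_splits: list[tuple[np.ndarray, np.ndarray]]
    assembled: AssembledData
    config: ValidationConfig
    failures: list[str] = field(default_factory=list)

    @property
    def n_success(self) -> int:
        return self.holdout_correlations.shape[0]


def _refit_and_project(
    Xa, Ya, Cx, Cy, opt, hold, cx, cy, n_modes, standardize, deconfound_mode,
    names=None,
):
    """Refit on the optimization set at a fixed pair, project the hold-out."""
    if names is not None:
        x_cols, y_cols, cx_cols, cy_cols = names
        Xa = pd.DataFrame(Xa, columns=x_cols)
        Ya = pd.DataFrame(Ya, columns=y_cols)
        Cx = pd.DataFrame(Cx, columns=cx_cols)
        Cy = pd.DataFrame(Cy, columns=cy_cols)
        Xa, Ya, Cx, Cy = (d.reset_index(drop=True) for d in (Xa, Ya, Cx, Cy))
        take = lambda df, rows: df.iloc[rows]  # noqa: E731
    else:
        take = lambda arr, rows: arr[rows]  # noqa: E731
    fit_rows = np.arange(Xa.shape[0]) if deconfound_mode == "all" else opt
    sx = fit_deconfounder(take(Xa, fit_rows), take(Cx, fit_rows), standardize=standardize)
    sy = fit_deconfounder(take(Ya, fit_rows), take(Cy, fit_rows), standardize=standardize)
    Xopt = apply_deconfounder(sx, take(Xa, opt), take(Cx, opt))
    Yopt = apply_deconfounder(sy, take(Ya, opt), take(Cy, opt))
    model = fit_rcca(Xopt, Yopt, cx, cy, n_modes)
    model.x_deconfounder = sx
    model.y_deconfounder = sy
    Xh = apply_deconfounder(sx, take(Xa, hold), take(Cx, hold)).to_numpy()
    Yh = apply_deconfounder(sy, take(Ya, hold), take(Cy, hold)).to_numpy()
    if Xh.shape[0] < 3:
        raise ValueError("hold-out side has fewer than 3 subjects")
    U = Xh @ model.wx
    V = Yh @ model.wy
    corrs = np.array(
        [np.corrcoef(U[:, k], V[:, k])[0, 1] for k in range(n_modes)]
    )
    return model, corrs, (Xopt, Yopt), (Xh, Yh)


def _mean_sd_frames(frames: list[pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    cat = pd.concat(frames, keys=range(len(frames)))
    grp = cat.groupby(level=1, sort=False)
    return grp.mean(), grp.std(ddof=1)


def run_multiple_holdout(
    bundle: CohortBundle,
    model_definition: ModelDefinition,
    config: ValidationConfig | None = None,
) -> tuple[pd.DataFrame, ModeSummary]:
    """Run the full nested hold-out framework for one model.

    Returns the per-repeat records (selected pair, hold-out correlation and
    redundancy per mode) and the :class:`ModeSummary` aggregate.  Loadings
    are computed on each repeat's optimization set by default and averaged
    after aligning each repeat's sign to the first successful repeat (by the
    sign of the weight-vector dot products).  A failed repeat is recorded and
    excluded with a warning.
    """
    config = config or ValidationConfig()
    asm = assemble_model_matrices(bundle, model_definition)
    Xa = asm.X.to_numpy(dtype=float)
    Ya = asm.Y.to_numpy(dtype=float)
    Cx = asm.x_confounds.to_numpy(dtype=float)
    Cy = asm.y_confounds.to_numpy(dtype=float)
    blocks = asm.blocks.to_numpy()
    m = config.n_modes

    master = np.random.SeedSequence(config.seed)
    split_seed, *repeat_seeds = master.spawn(config.n_outer + 1)
    outer_splits = make_block_splits(
        blocks, config.outer_fraction, config.n_outer, split_seed
    )

    rows = []
    ref_wx = ref_wy = None
    hold_corrs, redundancies, pairs = [], [], []
    xl_frames, xc_frames, yl_frames, yc_frames = [], [], [], []
    failures: list[str] = []
    for rep, (opt, hold) in enumerate(outer_splits):
        try:
            search = select_hyperparameters(
                Xa[opt],
                Ya[opt],
                Cx[opt],
                Cy[opt],
                blocks[opt],
                grid=config.grid,
                n_inner=config.n_inner,
                seed=repeat_seeds[rep],
                inner_fraction=config.inner_fraction,
                standardize=config.standardize,
                deconfound_mode=config.deconfound_mode,
            )
            cx, cy = search.selected
            model, corrs, (Xopt, Yopt), (Xh, Yh) = _refit_and_project(
                Xa, Ya, Cx, Cy, opt, hold, cx, cy, m,
                config.standardize, config.deconfound_mode,
                names=(
                    list(asm.X.columns), list(asm.Y.columns),
                    list(asm.x_confounds.columns), list(asm.y_confounds.columns),
                ),
            )
            basis = (Xopt, Yopt) if config.loadings_on == "optimization" else (
                pd.DataFrame(Xh, columns=Xopt.columns),
                pd.DataFrame(Yh, columns=Yopt.columns),
            )
            plain = RccaModel(
                wx=model.wx, wy=model.wy, cx=cx, cy=cy,
                train_correlations=model.train_correlations,
                x_features=list(Xopt.columns), y_features=list(Yopt.columns),
            )
            tab = compute_loadings(plain, basis[0], basis[1])
        except Exception as exc:  # noqa: BLE001 - repeat-level containment
            warnings.warn(f"outer repeat {rep} failed: {exc}", stacklevel=2)
            failures.append(f"repeat {rep}: {exc}")
            rows.append({"repeat": rep, "success": False})
            continue

        # sign-align loadings to the first successful repeat
        signs = np.ones(m)
        if ref_wx is None:
            ref_wx, ref_wy = model.wx.copy(), model.wy.copy()
        elif model.wx.shape == ref_wx.shape:
            for k in range(m):
                dot = model.wx[:, k] @ ref_wx[:, k] + model.wy[:, k] @ ref_wy[:, k]
                signs[k] = -1.0 if dot < 0 else 1.0
        xl_frames.append(tab.x_loadings * signs)
        xc_frames.append(tab.x_cross_loadings * signs)
        yl_frames.append(tab.y_loadings * signs)
        yc_frames.append(tab.y_cross_loadings * signs)

        red = np.array(
            [redundancy_index(tab.y_loadings.iloc[:, k], corrs[k]) for k in range(m)]
        )
        hold_corrs.append(corrs)
        redundancies.append(red)
        pairs.append([cx, cy])
        row = {"repeat": rep, "success": True, "cx": cx, "cy": cy}
        for k in range(m):
            row[f"holdout_r_mode_{k + 1}"] = corrs[k]
            row[f"redundancy_mode_{k + 1}"] = red[k]
        rows.append(row)

    if not hold_corrs:
        raise RuntimeError(f"every outer repeat failed: {failures[:3]}")
    hc = np.vstack(hold_corrs)
    rd = np.vstack(redundancies)
    pr = np.asarray(pairs)
    xl_mean, xl_sd = _mean_sd_frames(xl_frames)
    yl_mean, yl_sd = _mean_sd_frames(yl_frames)
    xc_mean, _ = _mean_sd_frames(xc_frames)
    yc_mean, _ = _mean_sd_frames(yc_frames)
    summary = ModeSummary(
        label=model_definition.label,
        n_modes=m,
        holdout_correlations=hc,
        mean_holdout=hc.mean(axis=0),
        sd_holdout=hc.std(axis=0, ddof=1) if hc.shape[0] > 1 else np.zeros(m),
        redundancy=rd,
        mean_redundancy=rd.mean(axis=0),
        selected_pairs=pr,
        median_pair=(float(np.median(pr[:, 0])), float(np.median(pr[:, 1]))),
        x_loadings_mean=xl_mean,
        x_loadings_sd=xl_sd,
        y_loadings_mean=yl_mean,
        y_loadings_sd=yl_sd,
        x_cross_loadings_mean=xc_mean,
        y_cross_loadings_mean=yc_mean,
        outer_splits=outer_splits,
        assembled=asm,
        config=config,
        failures=failures,
    )
    return pd.DataFrame(rows), summary
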