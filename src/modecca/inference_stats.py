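"""Permutation inference, model comparison and effect-size statistics.

Significance of a validated model is assessed by permuting the rows of Y
across subjects — one draw per permutation, applied consistently across all
outer folds — and re-running the 100 outer fits with the regularization pair
fixed to the median of the per-split selections.  The summary statistic on
both the observed and every null run is the Fisher-z mean of the hold-out
correlations, and the one-sided p-value uses the (1 + b) / (1 + m) convention.

Models within one sample are compared by corrected resampled t-tests on the
Fisher-z hold-out correlations (and redundancy indices): because the
optimization and hold-out sets overlap across repeats, the naive paired
t-test understates the variance, and the correction inflates it by
``1/K + n_test/n_train`` (Nadeau-Bengio).  Families of p-values are adjusted
by Benjamini-Hochberg FDR.

Also here: Spearman comparison of averaged loadings across samples
(replicability), and the group-difference statistics used to characterize
cohorts (Welch t with Cohen's d; Mann-Whitney U with rank-biserial r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deconfound import apply_deconfounder, fit_deconfounder
from .holdout_validation import ModeSummary
from .rcca_core import rcca_weights_from_covs

__all__ = [
    "PermutationResult",
    "TtestResult",
    "GroupDifference",
    "fisher_z_mean",
    "block_permutation",
    "permutation_test",
    "corrected_resampled_ttest",
    "fdr_adjust",
    "compare_loadings_across_samples",
    "rank_biserial_from_u",
    "group_difference_stats",
]


def fisher_z_mean(r_values) -> float:
    """tanh of the mean of atanh(r): the Fisher-z average correlation.

    Always lies between the smallest and largest input; requires |r| < 1.
    """
    r = np.asarray(r_values, dtype=float)
    if r.size == 0:
        raise ValueError("empty correlation vector")
    if np.any(np.abs(r) >= 1):
        raise ValueError("all |r| must be < 1 for the Fisher z transform")
    return float(np.tanh(np.arctanh(r).mean()))


def block_permutation(
    blocks, rng: np.random.Generator, mode: str = "within_between"
) -> np.ndarray:
    """One subject-level permutation respecting exchangeability blocks.

    ``within_between`` composes within-family shuffles with swaps of whole
    families of equal size (families remain intact as blocks); ``free``
    permutes all subjects unrestricted.  Returns ``perm`` such that the
    permuted Y is ``Y[perm]``.
    """
    labels = np.asarray(blocks)
    n = labels.size
    if mode == "free":
        return rng.permutation(n)
    if mode != "within_between":
        raise ValueError("mode must be 'within_between' or 'free'")
    uniq, codes = np.unique(labels, return_inverse=True)
    members = [np.flatnonzero(codes == f) for f in range(uniq.size)]
    sizes = np.array([m.size for m in members])
    perm = np.empty(n, dtype=int)
    for size in np.unique(sizes):
        fams = [members[f] for f in np.flatnonzero(sizes == size)]
        order = rng.permutation(len(fams))
        for src_pos, dst_pos in enumerate(order):
            perm[fams[src_pos]] = rng.permutation(fams[dst_pos])
    return perm


@dataclass
class PermutationResult:
    """Observed Fisher-z mean hold-out correlation versus its null."""

    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int


def permutation_test(
    summary: ModeSummary,
    n_perm: int = 5000,
    seed=0,
    block_mode: str = "within_between",
) -> PermutationResult:
    """Permutation significance of a validated model's first mode.

    Reuses the outer splits of the completed hold-out run; the
    regularization pair is fixed to the median of the per-split selections,
    so the inner search is not repeated under the null.  Each permutation
    draws one row mapping for Y, re-runs every outer fit (deconfounding
    refit on the permuted training rows), projects the hold-out set, and
    summarizes the hold-out correlations by their Fisher-z mean.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    asm = summary.assembled
    cfg = summary.config
    Xa = asm.X.to_numpy(dtype=float)
    Ya = asm.Y.to_numpy(dtype=float)
    Cx = asm.x_confounds.to_numpy(dtype=float)
    Cy = asm.y_confounds.to_numpy(dtype=float)
    blocks = asm.blocks.to_numpy()
    cx, cy = summary.median_pair
    observed = fisher_z_mean(summary.holdout_correlations[:, 0])
    n = Xa.shape[0]
    all_rows = np.arange(n)

    # the X side and its covariance structure do not depend on the permuted Y
    x_cache = []
    for opt, hold in summary.outer_splits:
        fit_rows = all_rows if cfg.deconfound_mode == "all" else opt
        sx = fit_deconfounder(Xa[fit_rows], Cx[fit_rows], standardize=cfg.standardize)
        Xopt = apply_deconfounder(sx, Xa[opt], Cx[opt]).to_numpy()
        Xh = apply_deconfounder(sx, Xa[hold], Cx[hold]).to_numpy()
        Xopt_c = Xopt - Xopt.mean(axis=0)
        Sxx = Xopt_c.T @ Xopt_c / (len(opt) - 1)
        x_cache.append((Xopt_c, Xh, Sxx))

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = block_permutation(blocks, rng, mode=block_mode)
        Yp = Ya[perm]
        rs = []
        for (opt, hold), (Xopt_c, Xh, Sxx) in zip(summary.outer_splits, x_cache):
            fit_rows = all_rows if cfg.deconfound_mode == "all" else opt
            sy = fit_deconfounder(
                Yp[fit_rows], Cy[fit_rows], standardize=cfg.standardize
            )
            Yopt = apply_deconfounder(sy, Yp[opt], Cy[opt]).to_numpy()
            Yh = apply_deconfounder(sy, Yp[hold], Cy[hold]).to_numpy()
            Yopt_c = Yopt - Yopt.mean(axis=0)
            m = len(opt)
            Syy = Yopt_c.T @ Yopt_c / (m - 1)
            Sxy = Xopt_c.T @ Yopt_c / (m - 1)
            wx, wy, _ = rcca_weights_from_covs(Sxx, Syy, Sxy, cx, cy, 1)
            u = Xh @ wx[:, 0]
            v = Yh @ wy[:, 0]
            if u.std() == 0 or v.std() == 0:
                continue
            rs.append(np.corrcoef(u, v)[0, 1])
        null[b] = fisher_z_mean(rs) if rs else np.nan
    valid = null[np.isfinite(null)]
    p = (1.0 + np.sum(valid >= observed)) / (1.0 + valid.size)
    return PermutationResult(observed=observed, null=null, p_value=float(p), n_perm=n_perm)


@dataclass
class TtestResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False


def corrected_resampled_ttest(
    scores_a, scores_b, n_train: int, n_test: int
) -> TtestResult:
    """Paired t-test over K repeated splits with Nadeau-Bengio correction.

    ``t = mean(d) / sqrt((1/K + n_test/n_train) * var(d))`` with K-1 degrees
    of freedom; the extra ``n_test/n_train`` term accounts for the overlap of
    training sets across repeats and strictly shrinks the evidence relative
    to the naive test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("scores must be equal-length vectors with K >= 2")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    K = a.size
    d = a - b
    var = d.var(ddof=1)
    factor = 1.0 / K + n_test / n_train
    if var == 0:
        if d.mean() == 0:
            return TtestResult(t=0.0, df=K - 1, p_value=1.0)
        t = np.inf if d.mean() > 0 else -np.inf
        return TtestResult(
            t=float(t), df=K - 1, p_value=float(np.finfo(float).tiny), degenerate=True
        )
    t = d.mean() / np.sqrt(factor * var)
    p = 2.0 * stats.t.sf(abs(t), df=K - 1)
    return TtestResult(t=float(t), df=K - 1, p_value=float(p))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_loadings_across_samples(
    loadings_a: pd.Series, loadings_b: pd.Series
) -> tuple[float, float]:
    """Spearman rank correlation of two samples' averaged loadings.

    Aligned by feature name over the intersection; at least three shared
    features are required.  Restrict the Series to one scope (e.g. the GMV
    parcels, or the pooled PSQI+ASR items) before calling.
    """
    a = pd.Series(loadings_a).dropna()
    b = pd.Series(loadings_b).dropna()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("loading vectors share no feature names")
    if len(common) < 3:
        raise ValueError(f"need >= 3 shared features, got {len(common)}")
    res = stats.spearmanr(a.loc[common], b.loc[common])
    return float(res.statistic), float(res.pvalue)


def rank_biserial_from_u(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation 2U/(n1*n2) - 1 for a Mann-Whitney U."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= U <= n1 * n2):
        raise ValueError(f"U must lie in [0, {n1 * n2}], got {U}")
    return 2.0 * U / (n1 * n2) - 1.0


@dataclass
class GroupDifference:
    """Welch t / Cohen's d and Mann-Whitney U / rank-biserial r for two groups."""

    t: float
    df: float
    p_t: float
    cohens_d: float
    u: float
    p_u: float
    rank_biserial: float
    degenerate: bool = False


def group_difference_stats(x, y) -> GroupDifference:
    """Both the parametric and the rank-based group comparison at once."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    degenerate = x.var(ddof=1) == 0 and y.var(ddof=1) == 0
    if degenerate:
        warnings.warn("zero variance in both samples; d undefined", stacklevel=2)
        t_stat, t_df, t_p, d = np.nan, np.nan, np.nan, np.nan
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t_stat, t_df, t_p = float(res.statistic), float(res.df), float(res.pvalue)
        pooled = np.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
        d = float((x.mean() - y.mean()) / pooled)
    mw = stats.mannwhitneyu(x, y, alternative="two-sided")
    rb = rank_biserial_from_u(float(mw.statistic), n1, n2)
    return GroupDifference(
        t=t_stat,
        df=t_df,
        p_t=t_p,
        cohens_d=d,
        u=float(mw.statistic),
        p_u=float(mw.pvalue),
        rank_biserial=rb,
        degenerate=degenerate,
    )
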