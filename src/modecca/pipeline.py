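"""Config-driven suite runner: the full experiment design, end to end.

For one cohort this runs the five-model suite (depressive symptoms, sleep
quality, grey-matter volume, behavior combined, all combined — each against
motor performance): multiple-hold-out validation, permutation significance,
averaged loadings and redundancy indices, then all pairwise model comparisons
within the sample by corrected resampled t-tests with FDR.  Across samples it
computes the Spearman replicability of averaged loadings per scope.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import standard_model_definitions
from .holdout_validation import ModeSummary, ValidationConfig, run_multiple_holdout
from .inference_stats import (
    PermutationResult,
    compare_loadings_across_samples,
    corrected_resampled_ttest,
    fdr_adjust,
    fisher_z_mean,
    permutation_test,
)
from .synthetic_cohort import CohortBundle

logger = logging.getLogger("modecca")

__all__ = ["SuiteConfig", "SuiteReport", "run_model_suite", "compare_samples"]

#: loading-replicability scopes: instrument items travel across cohorts,
#: motor tasks do not (those comparisons stay conceptual)
REPLICABILITY_SCOPES: dict[str, tuple[str, ...]] = {
    "gmv": ("gmv",),
    "psqi+asr": ("psqi", "asr"),
}


@dataclass
class SuiteConfig:
    """Configuration of one full per-sample analysis suite."""

    validation: ValidationConfig = field(default_factory=ValidationConfig)
    n_perm: int = 5000
    block_mode: str = "within_between"
    models: Sequence[str] | None = None  # None = all five
    n_modes: int = 1
    seed: int = 0
    extra_confounds: tuple[str, ...] = ()


@dataclass
class SuiteReport:
    """Everything one suite run computed, with provenance."""

    sample: str
    seed: int
    config_hash: str
    summaries: dict[str, ModeSummary]
    permutations: dict[str, PermutationResult]
    records: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    feature_domains: dict[str, str]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for label, s in self.summaries.items():
            perm = self.permutations.get(label)
            rows.append(
                {
                    "model": label,
                    "mean_holdout_r": s.mean_holdout[0],
                    "sd_holdout_r": s.sd_holdout[0],
                    "fisher_z_mean_r": fisher_z_mean(s.holdout_correlations[:, 0]),
                    "redundancy_index": s.mean_redundancy[0],
                    "median_cx": s.median_pair[0],
                    "median_cy": s.median_pair[1],
                    "n_repeats": s.n_success,
                    "perm_p": perm.p_value if perm else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def write(self, out_dir) -> None:
        """Serialize the report: structured summary plus CSV tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.summary_table()
        payload = {
            "sample": self.sample,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "models": json.loads(table.reset_index().to_json(orient="records")),
        }
        (out / "summary.json").write_text(json.dumps(payload, indent=2))
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        for label, s in self.summaries.items():
            tag = label.replace("+", "_")
            frames = []
            for side, mean, sd in (
                ("x", s.x_loadings_mean, s.x_loadings_sd),
                ("y", s.y_loadings_mean, s.y_loadings_sd),
            ):
                for k in range(s.n_modes):
                    col = f"mode_{k + 1}"
                    frames.append(
                        pd.DataFrame(
                            {
                                "feature": mean.index,
                                "domain": [
                                    self.feature_domains.get(f, side)
                                    for f in mean.index
                                ],
                                "mode": k + 1,
                                "mean_loading": mean[col].to_numpy(),
                                "sd_loading": sd[col].to_numpy(),
                            }
                        )
                    )
            pd.concat(frames).to_csv(out / f"loadings_{tag}.csv", index=False)
            pd.DataFrame(
                s.holdout_correlations,
                columns=[f"mode_{k + 1}" for k in range(s.n_modes)],
            ).to_csv(out / f"holdout_correlations_{tag}.csv", index=False)
            self.records[label].to_csv(out / f"records_{tag}.csv", index=False)


def _config_hash(config: SuiteConfig) -> str:
    text = repr(config)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_model_suite(
    bundle: CohortBundle, config: SuiteConfig | None = None, sample: str = "sample"
) -> SuiteReport:
    """Run every model of the suite on one cohort and compare them.

    Per model: multiple-hold-out validation, permutation p, averaged
    loadings, redundancy index.  Then all pairwise corrected resampled
    t-tests within the sample (Fisher-z hold-out correlations and redundancy
    indices), FDR-adjusted per metric.  A model failure is recorded and the
    suite continues.
    """
    config = config or SuiteConfig()
    defs = standard_model_definitions(
        bundle, n_modes=config.n_modes, extra_confounds=config.extra_confounds
    )
    if config.models is not None:
        unknown = [m for m in config.models if m not in defs]
        if unknown:
            raise ValueError(f"unknown model label(s): {unknown}")
        defs = {m: defs[m] for m in config.models}

    feature_domains: dict[str, str] = {}
    for dom, mat in bundle.domain_matrices.items():
        feature_domains.update({c: dom for c in mat.columns})

    master = np.random.SeedSequence(config.seed)
    model_seeds = master.spawn(len(defs))
    summaries: dict[str, ModeSummary] = {}
    permutations: dict[str, PermutationResult] = {}
    records: dict[str, pd.DataFrame] = {}
    for (label, mdef), seed_seq in zip(defs.items(), model_seeds):
        logger.info("running model %s", label)
        try:
            val_seed, perm_seed = (
                int(s) for s in seed_seq.generate_state(2) % (2**31 - 1)
            )
            vconf = replace(
                config.validation, seed=val_seed, n_modes=config.n_modes
            )
            recs, summary = run_multiple_holdout(bundle, mdef, vconf)
            summaries[label] = summary
            records[label] = recs
            if config.n_perm > 0:
                permutations[label] = permutation_test(
                    summary,
                    n_perm=config.n_perm,
                    seed=perm_seed,
                    block_mode=config.block_mode,
                )
        except Exception as exc:  # noqa: BLE001 - suite-level containment
            logger.warning("model %s failed: %s", label, exc)

    comparisons = _pairwise_comparisons(summaries)
    return SuiteReport(
        sample=sample,
        seed=config.seed,
        config_hash=_config_hash(config),
        summaries=summaries,
        permutations=permutations,
        records=records,
        comparisons=comparisons,
        feature_domains=feature_domains,
    )


def _pairwise_comparisons(summaries: Mapping[str, ModeSummary]) -> pd.DataFrame:
    """All within-sample model pairs, for correlations and redundancies."""
    labels = list(summaries)
    rows = []
    for metric in ("holdout_correlation", "redundancy_index"):
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                sa, sb = summaries[la], summaries[lb]
                k = min(sa.n_success, sb.n_success)
                if k < 2:
                    continue
                if metric == "holdout_correlation":
                    a = np.arctanh(np.clip(sa.holdout_correlations[:k, 0], -0.999999, 0.999999))
                    b = np.arctanh(np.clip(sb.holdout_correlations[:k, 0], -0.999999, 0.999999))
                else:
                    a = sa.redundancy[:k, 0]
                    b = sb.redundancy[:k, 0]
                n_opt = int(np.mean([len(o) for o, _ in sa.outer_splits]))
                n_hold = int(np.mean([len(h) for _, h in sa.outer_splits]))
                res = corrected_resampled_ttest(a, b, n_train=n_opt, n_test=n_hold)
                rows.append(
                    {
                        "metric": metric,
                        "model_a": la,
                        "model_b": lb,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p_value,
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = np.nan
        for metric in df["metric"].unique():
            mask = df["metric"] == metric
            df.loc[mask, "q"] = fdr_adjust(df.loc[mask, "p"].to_numpy())
    return df


def compare_samples(
    reports: Mapping[str, SuiteReport],
    model: str = "psqi+asr+gmv",
    mode: int = 1,
) -> pd.DataFrame:
    """Cross-sample replicability of averaged loadings, per scope.

    For every pair of samples and every scope (GMV parcels; pooled PSQI+ASR
    items) the averaged first-mode X-side loadings are compared by Spearman
    rank correlation over shared feature names; p-values are FDR-adjusted
    across all pairs and scopes.
    """
    col = f"mode_{mode}"
    rows = []
    names = list(reports)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = reports[a], reports[b]
            if model not in ra.summaries or model not in rb.summaries:
                continue
            la = ra.summaries[model].x_loadings_mean[col]
            lb = rb.summaries[model].x_loadings_mean[col]
            for scope, domains in REPLICABILITY_SCOPES.items():
                fa = la[[f for f in la.index if ra.feature_domains.get(f) in domains]]
                fb = lb[[f for f in lb.index if rb.feature_domains.get(f) in domains]]
                if len(fa.index.intersection(fb.index)) < 3:
                    continue
                rho, p = compare_loadings_across_samples(fa, fb)
                rows.append(
                    {"sample_a": a, "sample_b": b, "scope": scope, "rho": rho, "p": p}
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = fdr_adjust(df["p"].to_numpy())
    return df
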