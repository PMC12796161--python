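"""Synthetic multi-domain cohorts with a planted latent mode.

Real studies of this kind link questionnaire scores (sleep quality, depressive
symptoms), regional grey-matter volumes and motor-performance measures within
access-controlled cohorts (HCP, eNKI-RS).  This module generates cohorts with
the same statistical skeleton so the analysis machinery can be exercised and
calibrated end to end:

* a single latent factor ``z ~ N(0, 1)`` drives correlated variation across
  the X-side domains (PSQI components, ASR depression items, GMV parcels) and
  the Y-side domain (motor performance), at a population canonical correlation
  known in closed form;
* additive confound effects (age, age squared, sex, total intracranial
  volume);
* family-level clustering, so that block-respecting splitting and permutation
  can be tested;
* item ranges matching the questionnaires when integer clipping is enabled.

The generative model for subject ``i`` is::

    x_i = a * z_i + sum_c gamma_c^x * c_i  + f_{fam(i)} + eps_i,  eps ~ N(0, sigma_x^2 I)
    y_i = b * z_i + sum_c gamma_c^y * c_i  + f_{fam(i)} + eta_i,  eta ~ N(0, sigma_y^2 I)

with ``a``/``b`` the planted loading vectors and ``f`` an optional shared
family intercept (default SD 0).  Confound columns are standardized before
their effect vectors are applied, so effect sizes are on the per-SD scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_DOMAIN_SIZES",
    "X_DOMAIN_NAMES",
    "Y_DOMAIN_NAME",
    "ConfoundEffect",
    "SyntheticSpec",
    "CohortBundle",
    "assign_families",
    "generate_cohort",
    "population_canonical_correlation",
    "spec_to_yaml",
    "spec_from_yaml",
]

#: Feature counts of the study instruments: the PSQI has seven component
#: scores, the ASR depression scale (sleep items excluded) has eleven items,
#: the whole-brain parcellation has 262 regions, and the motor battery has
#: four measures per cohort (strength, endurance, gait speed, processing
#: speed in the HCP samples).
DEFAULT_DOMAIN_SIZES: dict[str, int] = {"psqi": 7, "asr": 11, "gmv": 262, "motor": 4}

X_DOMAIN_NAMES: tuple[str, ...] = ("psqi", "asr", "gmv")
Y_DOMAIN_NAME: str = "motor"

_PSQI_COMPONENTS = [
    "psqi_subjective_quality",
    "psqi_latency",
    "psqi_duration",
    "psqi_efficiency",
    "psqi_disturbances",
    "psqi_medication",
    "psqi_daytime_dysfunction",
]
_MOTOR_DEFAULT = [
    "motor_grip_strength",
    "motor_endurance",
    "motor_gait_speed",
    "motor_processing_speed",
]

#: integer score range per questionnaire-like domain, used only when
#: ``integer_clip`` is on.
_CLIP_RANGES = {"psqi": (0, 3), "asr": (0, 2)}


def _feature_names(domain: str, size: int) -> list[str]:
    if domain == "psqi" and size == len(_PSQI_COMPONENTS):
        return list(_PSQI_COMPONENTS)
    if domain == "motor" and size == len(_MOTOR_DEFAULT):
        return list(_MOTOR_DEFAULT)
    width = max(2, len(str(size)))
    if domain == "gmv":
        return [f"gmv_region_{i + 1:0{width}d}" for i in range(size)]
    return [f"{domain}_{i + 1:0{width}d}" for i in range(size)]


@dataclass(frozen=True)
class ConfoundEffect:
    """Per-feature additive effect of one confound on the X and Y sides.

    Entries are on the per-SD scale of the confound (the generator
    standardizes each confound column before applying the effect).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_subjects
        Cohort size.
    x_loadings, y_loadings
        Planted loading vectors ``a`` (over the concatenated psqi/asr/gmv
        features, in that order) and ``b`` (over the motor features).
    x_noise_sd, y_noise_sd
        Isotropic noise SDs ``sigma_x``, ``sigma_y`` (> 0).
    confound_effects
        Map confound name -> :class:`ConfoundEffect`.  Confound names must be
        among ``age``, ``age2``, ``sex``, ``tiv``.
    n_families
        If given, exactly this many families are formed with sizes inside
        ``family_size_range``; otherwise family sizes are drawn greedily.
    family_size_range
        Inclusive ``(min, max)`` family size.
    family_effect_sd
        SD of a shared Gaussian intercept added to every feature of every
        member of a family (default 0: independent subjects).
    age_range
        Uniform age range in years.
    domain_sizes
        Feature count per domain; defaults to the study instruments.
    integer_clip
        Round and clip questionnaire domains to their item ranges (off by
        default; the analysis operates on real matrices).
    seed
        Seed for all randomness in :func:`generate_cohort`.
    """

    n_subjects: int
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_noise_sd: float = 1.0
    y_noise_sd: float = 1.0
    confound_effects: Mapping[str, ConfoundEffect] = field(default_factory=dict)
    n_families: int | None = None
    family_size_range: tuple[int, int] = (1, 1)
    family_effect_sd: float = 0.0
    age_range: tuple[float, float] = (22.0, 37.0)
    domain_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_SIZES)
    )
    integer_clip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.x_loadings = np.asarray(self.x_loadings, dtype=float)
        self.y_loadings = np.asarray(self.y_loadings, dtype=float)
        self.domain_sizes = dict(self.domain_sizes)
        self.validate()

    @property
    def n_x_features(self) -> int:
        return sum(self.domain_sizes[d] for d in X_DOMAIN_NAMES)

    @property
    def n_y_features(self) -> int:
        return self.domain_sizes[Y_DOMAIN_NAME]

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.x_noise_sd <= 0 or self.y_noise_sd <= 0:
            raise ValueError("noise SDs must be strictly positive")
        for name in list(X_DOMAIN_NAMES) + [Y_DOMAIN_NAME]:
            if name not in self.domain_sizes:
                raise ValueError(f"domain_sizes missing domain {name!r}")
        if self.x_loadings.shape != (self.n_x_features,):
            raise ValueError(
                f"x_loadings has length {self.x_loadings.size}, expected "
                f"{self.n_x_features} (psqi+asr+gmv)"
            )
        if self.y_loadings.shape != (self.n_y_features,):
            raise ValueError(
                f"y_loadings has length {self.y_loadings.size}, expected "
                f"{self.n_y_features} (motor)"
            )
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValueError("family_size_range must satisfy 1 <= min <= max")
        if lo > self.n_subjects:
            raise ValueError(
                f"impossible family partition: minimum family size {lo} exceeds "
                f"n_subjects {self.n_subjects}"
            )
        if self.n_families is not None:
            nf = self.n_families
            if nf <= 0:
                raise ValueError("n_families must be positive")
            if not (nf * lo <= self.n_subjects <= nf * hi):
                raise ValueError(
                    f"cannot partition {self.n_subjects} subjects into {nf} "
                    f"families with sizes in [{lo}, {hi}]"
                )
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing pair")
        for cname, eff in self.confound_effects.items():
            if cname not in ("age", "age2", "sex", "tiv"):
                raise ValueError(f"unknown confound {cname!r}")
            if eff.x.shape != (self.n_x_features,) or eff.y.shape != (self.n_y_features,):
                raise ValueError(f"confound effect {cname!r} has wrong length")

    def has_confound_effects(self) -> bool:
        return any(
            np.any(eff.x != 0) or np.any(eff.y != 0)
            for eff in self.confound_effects.values()
        )


@dataclass
class CohortBundle:
    """Subject-aligned domain matrices, confounds and family labels.

    All tables share the same subject index (in the same order); the
    ``age2`` confound column is the square of ``age``.
    """

    subject_ids: list[str]
    domain_matrices: dict[str, pd.DataFrame]
    confounds: pd.DataFrame
    family_ids: pd.Series

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        idx = pd.Index(self.subject_ids, name="subject_id")
        if idx.has_duplicates:
            raise ValueError("subject_ids must be unique")
        for name, mat in self.domain_matrices.items():
            if not mat.index.equals(idx):
                raise ValueError(f"domain {name!r} is not row-aligned to subject_ids")
            if mat.isna().any().any():
                # assembly drops missing values listwise; a freshly generated
                # bundle must be complete
                pass
        if not self.confounds.index.equals(idx):
            raise ValueError("confounds not row-aligned to subject_ids")
        if not self.family_ids.index.equals(idx):
            raise ValueError("family_ids not row-aligned to subject_ids")
        if "age" in self.confounds and "age2" in self.confounds:
            if not np.allclose(
                self.confounds["age2"], self.confounds["age"] ** 2, atol=1e-8
            ):
                raise ValueError("age2 column must equal age squared")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def assign_families(
    n_subjects: int, family_size_range: tuple[int, int], seed: int
) -> list[str]:
    """Partition ``n_subjects`` into families with sizes in the given range.

    Sizes are drawn uniformly from the inclusive range until the cohort is
    exhausted; at most one final remainder family may fall below the minimum
    size.  Deterministic given ``seed``.
    """
    lo, hi = int(family_size_range[0]), int(family_size_range[1])
    if not (1 <= lo <= hi):
        raise ValueError("family_size_range must satisfy 1 <= min <= max")
    if lo > n_subjects:
        raise ValueError(
            f"impossible family partition: minimum family size {lo} exceeds "
            f"n_subjects {n_subjects}"
        )
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    remaining = n_subjects
    while remaining > 0:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, remaining)
        sizes.append(size)
        remaining -= size
    width = max(4, len(str(len(sizes))))
    labels: list[str] = []
    for fam, size in enumerate(sizes):
        labels.extend([f"F{fam + 1:0{width}d}"] * size)
    return labels


def _exact_family_sizes(
    n_subjects: int, n_families: int, size_range: tuple[int, int], rng: np.random.Generator
) -> list[int]:
    """Exactly ``n_families`` sizes within range summing to ``n_subjects``."""
    lo, hi = size_range
    sizes = np.full(n_families, lo, dtype=int)
    excess = n_subjects - n_families * lo
    # distribute the excess one subject at a time over families with headroom
    while excess > 0:
        open_slots = np.flatnonzero(sizes < hi)
        sizes[rng.choice(open_slots)] += 1
        excess -= 1
    return sizes.tolist()


def generate_cohort(spec: SyntheticSpec) -> CohortBundle:
    """Draw one cohort from the single-factor linear-Gaussian model.

    Reproducible: identical ``spec`` (including its seed) gives a
    bit-identical bundle.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    # family structure
    if spec.n_families is not None:
        fam_sizes = _exact_family_sizes(
            n, spec.n_families, spec.family_size_range, rng
        )
        width = max(4, len(str(len(fam_sizes))))
        family_labels: list[str] = []
        for fam, size in enumerate(fam_sizes):
            family_labels.extend([f"F{fam + 1:0{width}d}"] * size)
    else:
        family_labels = assign_families(
            n, spec.family_size_range, int(rng.integers(0, 2**31 - 1))
        )

    subject_ids = [f"S{i + 1:06d}" for i in range(n)]
    idx = pd.Index(subject_ids, name="subject_id")

    # confounds: age uniform, sex balanced binary, TIV log-normal around a
    # plausible 1450 cm^3, age2 derived
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = np.zeros(n)
    sex[: n // 2] = 1.0
    sex = sex[rng.permutation(n)]
    tiv = np.exp(rng.normal(np.log(1450.0), 0.08, size=n))
    confounds = pd.DataFrame(
        {"age": age, "age2": age**2, "sex": sex, "tiv": tiv}, index=idx
    )

    z = rng.standard_normal(n)
    p, q = spec.n_x_features, spec.n_y_features
    X = np.outer(z, spec.x_loadings) + rng.standard_normal((n, p)) * spec.x_noise_sd
    Y = np.outer(z, spec.y_loadings) + rng.standard_normal((n, q)) * spec.y_noise_sd

    for cname, eff in spec.confound_effects.items():
        col = confounds[cname].to_numpy()
        col_std = (col - col.mean()) / col.std() if col.std() > 0 else col - col.mean()
        X += np.outer(col_std, eff.x)
        Y += np.outer(col_std, eff.y)

    if spec.family_effect_sd > 0:
        fam_codes, uniques = pd.factorize(pd.Series(family_labels))
        intercepts = rng.normal(0.0, spec.family_effect_sd, size=len(uniques))
        X += intercepts[fam_codes][:, None]
        Y += intercepts[fam_codes][:, None]

    domain_matrices: dict[str, pd.DataFrame] = {}
    offset = 0
    for dom in X_DOMAIN_NAMES:
        size = spec.domain_sizes[dom]
        block = X[:, offset : offset + size]
        if spec.integer_clip and dom in _CLIP_RANGES:
            lo, hi = _CLIP_RANGES[dom]
            centre = (lo + hi) / 2
            block = np.clip(np.rint(block + centre), lo, hi)
        domain_matrices[dom] = pd.DataFrame(
            block, index=idx, columns=_feature_names(dom, size)
        )
        offset += size
    domain_matrices[Y_DOMAIN_NAME] = pd.DataFrame(
        Y, index=idx, columns=_feature_names(Y_DOMAIN_NAME, q)
    )

    return CohortBundle(
        subject_ids=subject_ids,
        domain_matrices=domain_matrices,
        confounds=confounds,
        family_ids=pd.Series(family_labels, index=idx, name="family_id"),
    )


def population_canonical_correlation(spec: SyntheticSpec) -> float:
    """First canonical correlation implied by the planted single-factor model.

    With ``x = a z + eps`` and ``y = b z + eta`` the population covariance is
    ``Sxx = a a' + sigma_x^2 I``, ``Syy = b b' + sigma_y^2 I`` and
    ``Sxy = a b'``; its leading canonical correlation is

        rho = sqrt(|a|^2 / (|a|^2 + sigma_x^2)) * sqrt(|b|^2 / (|b|^2 + sigma_y^2))

    (the canonical directions are along ``a`` and ``b``).  Only valid when no
    confound or family effects are planted.
    """
    if spec.has_confound_effects():
        raise ValueError(
            "closed-form canonical correlation is only valid with zero confound effects"
        )
    if spec.family_effect_sd > 0:
        raise ValueError(
            "closed-form canonical correlation is only valid without family effects"
        )
    a2 = float(spec.x_loadings @ spec.x_loadings)
    b2 = float(spec.y_loadings @ spec.y_loadings)
    return float(
        np.sqrt(a2 / (a2 + spec.x_noise_sd**2)) * np.sqrt(b2 / (b2 + spec.y_noise_sd**2))
    )


# -- configuration round-trip ------------------------------------------------


def spec_to_yaml(spec: SyntheticSpec, path) -> None:
    """Serialize a :class:`SyntheticSpec` to a YAML file."""
    payload = asdict(spec)
    payload["x_loadings"] = spec.x_loadings.tolist()
    payload["y_loadings"] = spec.y_loadings.tolist()
    payload["family_size_range"] = list(spec.family_size_range)
    payload["age_range"] = list(spec.age_range)
    payload["confound_effects"] = {
        name: {"x": eff.x.tolist(), "y": eff.y.tolist()}
        for name, eff in spec.confound_effects.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` written by :func:`spec_to_yaml`."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    payload["x_loadings"] = np.asarray(payload["x_loadings"], dtype=float)
    payload["y_loadings"] = np.asarray(payload["y_loadings"], dtype=float)
    payload["family_size_range"] = tuple(payload["family_size_range"])
    payload["age_range"] = tuple(payload["age_range"])
    payload["confound_effects"] = {
        name: ConfoundEffect(x=np.asarray(d["x"]), y=np.asarray(d["y"]))
        for name, d in payload["confound_effects"].items()
    }
    return SyntheticSpec(**payload)
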