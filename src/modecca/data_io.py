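"""Reading, assembling and writing subject-aligned phenotype tables.

Cohort data are delimited text tables (comma default, tab accepted) with a
header row and ``subject_id`` as the first column: one table per questionnaire
or imaging domain, one for the confounds, one mapping subjects to families.
Model definitions pick domains and confounds; assembly concatenates the X-side
domains in declared order, drops subjects with any missing value listwise, and
keeps everything row-aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import CohortBundle, X_DOMAIN_NAMES, Y_DOMAIN_NAME

__all__ = [
    "DomainSpec",
    "ModelDefinition",
    "AssembledData",
    "read_phenotype_table",
    "assemble_model_matrices",
    "write_cohort",
    "read_cohort",
    "combine_cohorts",
    "standard_model_definitions",
]

#: confounds applied to every model
BASE_CONFOUNDS = ("age", "age2", "sex")


@dataclass(frozen=True)
class DomainSpec:
    """One variable domain: its feature columns and the confounds to remove."""

    name: str
    columns: tuple[str, ...]
    confound_names: tuple[str, ...] = BASE_CONFOUNDS

    def __post_init__(self) -> None:
        if len(self.columns) == 0:
            raise ValueError(f"domain {self.name!r} has no columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"domain {self.name!r} has duplicate columns")


@dataclass(frozen=True)
class ModelDefinition:
    """One rCCA model: X-side domains versus the motor-performance domain."""

    x_domains: tuple[DomainSpec, ...]
    y_domain: DomainSpec
    n_modes: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        x_cols = [c for d in self.x_domains for c in d.columns]
        if set(x_cols) & set(self.y_domain.columns):
            raise ValueError("X and Y domains share columns")
        if self.n_modes < 1:
            raise ValueError("n_modes must be positive")
        if self.n_modes > min(len(x_cols), len(self.y_domain.columns)):
            raise ValueError("n_modes exceeds min(X features, Y features)")
        if not self.label:
            object.__setattr__(
                self, "label", "+".join(d.name for d in self.x_domains)
            )

    @property
    def x_columns(self) -> list[str]:
        return [c for d in self.x_domains for c in d.columns]

    @property
    def x_confound_names(self) -> list[str]:
        seen: list[str] = []
        for d in self.x_domains:
            for c in d.confound_names:
                if c not in seen:
                    seen.append(c)
        return seen


def read_phenotype_table(
    path, expected_columns: Sequence[str] | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read one delimited table into a DataFrame indexed by ``subject_id``.

    ``sep=None`` sniffs comma vs tab from the header line.  Missing cells
    remain NaN (flagged, not dropped here).  Raises on absent expected
    columns or duplicated subject ids, naming the offender.
    """
    path = Path(path)
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] != "subject_id":
        raise ValueError(
            f"{path.name}: first column must be 'subject_id', got {df.columns[0]!r}"
        )
    df = df.set_index("subject_id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path.name}: duplicate subject id(s): {dupes}")
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing expected column(s): {missing}")
        df = df[list(expected_columns)]
    return df


@dataclass
class AssembledData:
    """Row-aligned matrices for one model, after listwise deletion."""

    X: pd.DataFrame
    Y: pd.DataFrame
    x_confounds: pd.DataFrame
    y_confounds: pd.DataFrame
    blocks: pd.Series
    n_dropped: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.X)


def assemble_model_matrices(bundle: CohortBundle, model: ModelDefinition) -> AssembledData:
    """Build X / Y / confound matrices and family blocks for one model.

    X concatenates the model's X-side domains in declared order.  Subjects
    with any missing value in any used column (features or confounds) are
    dropped listwise and the drop count reported.
    """
    all_features = pd.concat(bundle.domain_matrices.values(), axis=1)
    missing_cols = [
        c
        for c in model.x_columns + list(model.y_domain.columns)
        if c not in all_features.columns
    ]
    if missing_cols:
        raise ValueError(f"bundle lacks model column(s): {missing_cols}")
    used_conf = sorted(
        set(model.x_confound_names) | set(model.y_domain.confound_names),
        key=lambda c: list(bundle.confounds.columns).index(c),
    )
    missing_conf = [c for c in used_conf if c not in bundle.confounds.columns]
    if missing_conf:
        raise ValueError(f"bundle lacks confound column(s): {missing_conf}")

    X = all_features[model.x_columns]
    Y = all_features[list(model.y_domain.columns)]
    conf = bundle.confounds[used_conf]
    complete = ~(
        X.isna().any(axis=1) | Y.isna().any(axis=1) | conf.isna().any(axis=1)
    )
    n_dropped = int((~complete).sum())
    notes: list[str] = []
    if n_dropped:
        notes.append(f"dropped {n_dropped} subject(s) with missing values (listwise)")
    X, Y, conf = X[complete], Y[complete], conf[complete]
    blocks = bundle.family_ids[complete]
    if len(X) < len(model.x_columns):
        msg = (
            f"retained subjects ({len(X)}) fewer than X features "
            f"({len(model.x_columns)}); regularized CCA handles p > n but "
            "results may be unstable"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    return AssembledData(
        X=X,
        Y=Y,
        x_confounds=conf[model.x_confound_names],
        y_confounds=conf[list(model.y_domain.confound_names)],
        blocks=blocks,
        n_dropped=n_dropped,
        warnings=notes,
    )


def standard_model_definitions(
    bundle: CohortBundle, n_modes: int = 1, extra_confounds: Sequence[str] = ()
) -> dict[str, ModelDefinition]:
    """The five-model suite: asr, psqi, gmv, psqi+asr, psqi+asr+gmv vs motor.

    Total intracranial volume is added as a confound only for models whose X
    side includes grey-matter volume; ``extra_confounds`` (e.g. cohort
    indicator columns) are appended everywhere.
    """
    extra = tuple(extra_confounds)
    base = BASE_CONFOUNDS + extra

    def dom(name: str, with_tiv: bool = False) -> DomainSpec:
        conf = base + (("tiv",) if with_tiv else ())
        return DomainSpec(
            name=name,
            columns=tuple(bundle.domain_matrices[name].columns),
            confound_names=conf,
        )

    motor = dom(Y_DOMAIN_NAME)
    suites: dict[str, ModelDefinition] = {}
    combos = {
        "asr": ("asr",),
        "psqi": ("psqi",),
        "gmv": ("gmv",),
        "psqi+asr": ("psqi", "asr"),
        "psqi+asr+gmv": ("psqi", "asr", "gmv"),
    }
    for label, names in combos.items():
        with_tiv = "gmv" in names
        suites[label] = ModelDefinition(
            x_domains=tuple(dom(n, with_tiv=with_tiv) for n in names),
            y_domain=motor,
            n_modes=n_modes,
            label=label,
        )
    return suites


# -- cohort table round-trip -------------------------------------------------


def write_cohort(bundle: CohortBundle, directory, sep: str = ",") -> None:
    """Write one table per domain plus confounds and the family map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mat in bundle.domain_matrices.items():
        mat.to_csv(directory / f"{name}.csv", sep=sep)
    bundle.confounds.to_csv(directory / "confounds.csv", sep=sep)
    bundle.family_ids.to_frame().to_csv(directory / "families.csv", sep=sep)


def read_cohort(directory, domains: Sequence[str] | None = None) -> CohortBundle:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    if domains is None:
        domains = [
            p.stem
            for p in sorted(directory.glob("*.csv"))
            if p.stem not in ("confounds", "families")
        ]
        # keep canonical ordering when present
        order = list(X_DOMAIN_NAMES) + [Y_DOMAIN_NAME]
        domains = sorted(domains, key=lambda d: order.index(d) if d in order else 99)
    mats = {name: read_phenotype_table(directory / f"{name}.csv") for name in domains}
    confounds = read_phenotype_table(directory / "confounds.csv")
    families = read_phenotype_table(directory / "families.csv")["family_id"]
    first = next(iter(mats.values()))
    subject_ids = [str(s) for s in first.index]
    return CohortBundle(
        subject_ids=subject_ids,
        domain_matrices=mats,
        confounds=confounds,
        family_ids=families,
    )


def combine_cohorts(bundles: dict[str, CohortBundle]) -> CohortBundle:
    """Stack cohorts, adding one-hot cohort confound columns.

    The first cohort (insertion order) is the reference level and gets no
    indicator column, keeping the confound design full-rank alongside the
    intercept.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two cohorts to combine")
    labels = list(bundles)
    doms = list(next(iter(bundles.values())).domain_matrices)
    parts_dom = {d: [] for d in doms}
    parts_conf, parts_fam, subject_ids = [], [], []
    for label, b in bundles.items():
        prefix = f"{label}:"
        idx = pd.Index([prefix + s for s in b.subject_ids], name="subject_id")
        for d in doms:
            m = b.domain_matrices[d].copy()
            m.index = idx
            parts_dom[d].append(m)
        conf = b.confounds.copy()
        conf.index = idx
        for other in labels[1:]:
            conf[f"cohort_{other}"] = 1.0 if other == label else 0.0
        parts_conf.append(conf)
        fam = b.family_ids.copy()
        fam.index = idx
        parts_fam.append(prefix + fam.astype(str))
        subject_ids.extend(idx)
    return CohortBundle(
        subject_ids=[str(s) for s in subject_ids],
        domain_matrices={d: pd.concat(parts_dom[d]) for d in doms},
        confounds=pd.concat(parts_conf),
        family_ids=pd.concat(parts_fam).rename("family_id"),
    )
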