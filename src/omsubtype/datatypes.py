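"""Core containers shared across the subtyping pipeline.

Subjects are always rows, molecular features columns, and values are assumed
log-scale continuous measurements (assay-level normalisation happens upstream).
Provenance of each omic matrix is tracked by three monotone flags:
``adjusted`` (cell-composition regressed out) -> ``standardized`` (z-scored)
-> ``filtered`` (covariate filter applied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("omsubtype")

OUTLIER_LABEL = -1

VariableKind = str  # "continuous" | "binary" | "categorical"
KINDS = ("continuous", "binary", "categorical")
ROLES = ("cell_count", "filter", "test")


class FormatError(ValueError):
    """Malformed input file (duplicate IDs, non-numeric cells, ...)."""


class SchemaError(ValueError):
    """Clinical schema violates a declared-role invariant."""


@dataclass
class OmicsMatrix:
    """One omic layer: an n_subjects x n_features continuous matrix."""

    omic_name: str
    subject_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    adjusted: bool = False
    standardized: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_ids)} features"
            )
        for name, ids in (("subject", self.subject_ids), ("feature", self.feature_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} ID: {i!r}")
                seen.add(i)
        if self.filtered and not self.standardized:
            raise ValueError("a filtered matrix must also be standardized")
        if self.standardized and not self.adjusted:
            raise ValueError("a standardized matrix must also be adjusted")
        if self.adjusted and not np.all(np.isfinite(self.values)):
            raise ValueError("adjusted matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.feature_ids,
        )

    def with_values(self, values: np.ndarray, **flags) -> "OmicsMatrix":
        return replace(self, values=np.asarray(values, dtype=float), **flags)

    def select_features(self, feature_ids: list[str], **flags) -> "OmicsMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return replace(
            self, feature_ids=list(feature_ids), values=self.values[:, idx], **flags
        )

    def select_subjects(self, subject_ids: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return replace(self, subject_ids=list(subject_ids), values=self.values[idx])


@dataclass
class ClinicalVariable:
    name: str
    kind: VariableKind
    roles: frozenset
    values: pd.Series  # indexed by subject_id, NaN = missing

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        self.roles = frozenset(self.roles)
        bad = self.roles - set(ROLES)
        if bad:
            raise SchemaError(f"unknown role(s) {sorted(bad)} for {self.name!r}")
        if "cell_count" in self.roles and self.kind != "continuous":
            raise SchemaError(
                f"cell_count variable {self.name!r} must be continuous, got {self.kind}"
            )
        if "cell_count" in self.roles and "filter" in self.roles:
            raise SchemaError(
                f"{self.name!r}: cell_count variables are excluded from the filter set"
            )


@dataclass
class ClinicalTable:
    """Subjects x typed clinical variables with declared roles.

    Roles drive how each variable is used: ``cell_count`` variables feed the
    cell-composition regression, ``filter`` variables the covariate filter, and
    ``test`` variables the subtype association tests.
    """

    subject_ids: list[str]
    variables: list[ClinicalVariable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate clinical variable names")
        index = pd.Index(self.subject_ids)
        if index.has_duplicates:
            raise FormatError("duplicate subject IDs in clinical table")
        for v in self.variables:
            v.values = v.values.reindex(index)

    def by_role(self, role: str) -> list[ClinicalVariable]:
        return [v for v in self.variables if role in v.roles]

    def __getitem__(self, name: str) -> ClinicalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def cell_count_matrix(self, subject_ids: list[str]) -> pd.DataFrame:
        cells = self.by_role("cell_count")
        return pd.DataFrame(
            {v.name: v.values.reindex(subject_ids).to_numpy() for v in cells},
            index=subject_ids,
        )

    def subset(self, subject_ids: list[str]) -> "ClinicalTable":
        return ClinicalTable(
            subject_ids=list(subject_ids),
            variables=[
                ClinicalVariable(v.name, v.kind, v.roles, v.values.reindex(subject_ids))
                for v in self.variables
            ],
        )


@dataclass
class AnnotationDB:
    """Category -> (hierarchy level, member feature IDs); GMT-derived."""

    categories: dict = field(default_factory=dict)  # name -> set[str]
    levels: dict = field(default_factory=dict)  # name -> int

    def add(self, name: str, members: set, level: int = 1) -> None:
        if name in self.categories:
            logger.warning("annotation category %r listed twice; members unioned", name)
            self.categories[name] |= set(members)
        else:
            self.categories[name] = set(members)
            self.levels[name] = int(level)

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class ProjectedCluster:
    members: np.ndarray  # integer row indices into the clustered matrix
    dims: tuple  # relevant dimension indices, sorted
    medoid: np.ndarray  # medoid coordinates (full embedding space)
    quality: float


@dataclass
class Clustering:
    """Cluster labels over one set of points; -1 marks outliers.

    ``clusters[i]`` describes the cluster carrying label ``i``. For projected
    clusterings each cluster has a relevant dimension subset and every member
    lies within the width ``w`` of the medoid on those dimensions; for k-means
    all dimensions are relevant and there are no outliers.
    """

    labels: np.ndarray
    clusters: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list:
        return [len(c.members) for c in self.clusters]

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER_LABEL))

    def members_of(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)
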