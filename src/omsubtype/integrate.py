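"""Multi-omics integration at two stages.

Early (pre-clustering) integration concatenates equal-width per-omic
embeddings over the shared subjects and clusters the joined space; late
(post-clustering) integration combines per-omic binary subtype labels into
combination subtypes (up to 2^m for m omics) and materializes the contrast
groups of interest: the all-large group and, per omic, the subjects small in
exactly that omic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mineclus
from .assoc_enrich import test_clinical_associations
from .datatypes import ClinicalTable, Clustering
from .dimred import Embedding

logger = logging.getLogger("omsubtype")


@dataclass
class IntegrationResult:
    subject_ids: list  # shared subjects, outlier-free in every omic
    omics: list  # omic names in combination-label order
    combination: pd.Series  # subject -> e.g. "L-S-L"
    contrast_groups: dict  # group name -> list of subject IDs
    n_excluded_outliers: int = 0
    associations: pd.DataFrame | None = None

    def counts(self) -> pd.Series:
        """Combination-subtype sizes (upset-plot-ready)."""
        return self.combination.value_counts().sort_index()


def concat_embeddings(embeddings: list) -> Embedding:
    """Join equal-width embeddings by subject ID over the intersection.

    Each block is re-standardized column-wise (mean 0, unit variance) before
    concatenation so no omic dominates by scale; the equal-width requirement
    does the rest. Result width = m x number of omics.
    """
    if len(embeddings) < 2:
        raise ValueError("need at least 2 embeddings to integrate")
    widths = {e.m for e in embeddings}
    if len(widths) != 1:
        raise ValueError(
            f"all omics must contribute equal-length embeddings, got widths "
            f"{sorted(e.m for e in embeddings)}"
        )
    shared = set(embeddings[0].subject_ids)
    for e in embeddings[1:]:
        shared &= set(e.subject_ids)
    if not shared:
        raise ValueError("no subjects shared across all embeddings")
    subjects = [s for s in embeddings[0].subject_ids if s in shared]
    blocks = []
    for e in embeddings:
        pos = {s: i for i, s in enumerate(e.subject_ids)}
        block = e.coordinates[[pos[s] for s in subjects]]
        block = block - block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        blocks.append(block / sd)
    coords = np.hstack(blocks)
    return Embedding(
        method="concat",
        subject_ids=subjects,
        m=coords.shape[1],
        coordinates=coords,
        diagnostics={"block_widths": [e.m for e in embeddings],
                     "block_methods": [e.method for e in embeddings]},
    )


def pre_cluster_integrate(
    embeddings: list,
    k_range=range(2, 11),
    w_grid=None,
    min_small_silhouette: float = 0.10,
    seed: int = 0,
    **mineclus_kwargs,
):
    """Early integration: systematic (w, k) clustering of the joined embedding.

    A single embedding short-circuits to clustering that embedding alone.
    Returns (SelectionResult, joined Embedding).
    """
    joined = embeddings[0] if len(embeddings) == 1 else concat_embeddings(embeddings)
    selection = mineclus.select_params(
        joined.coordinates,
        w_grid=w_grid,
        k_range=k_range,
        min_small_silhouette=min_small_silhouette,
        seed=seed,
        **mineclus_kwargs,
    )
    if selection.chosen is not None:
        selection.chosen.subject_ids = list(joined.subject_ids)
    return selection, joined


def _large_small_coding(clustering: Clustering) -> dict:
    """Map cluster label -> 'L'/'S'; larger cluster is L, ties to the lower
    label index."""
    if clustering.n_clusters != 2:
        raise ValueError(
            f"post-clustering combination needs exactly 2 clusters, "
            f"got {clustering.n_clusters}"
        )
    sizes = clustering.sizes()
    large = 0 if sizes[0] >= sizes[1] else 1
    return {large: "L", 1 - large: "S"}


def post_cluster_combine(clusterings: list, omic_names: list) -> IntegrationResult:
    """Late integration: combination subtypes from per-omic binary clusterings.

    Subjects must appear in every clustering; anyone who is an outlier in any
    omic is excluded (count reported). With all joint patterns present, m
    binary clusterings yield 2^m combination subtypes.
    """
    if len(clusterings) < 2:
        raise ValueError("need at least 2 clusterings to combine")
    for c in clusterings:
        if c.subject_ids is None:
            raise ValueError("clusterings must carry subject IDs to be combined")
    shared = set(clusterings[0].subject_ids)
    for c in clusterings[1:]:
        shared &= set(c.subject_ids)
    if not shared:
        raise ValueError("no subjects shared across all clusterings")
    ordered = [s for s in clusterings[0].subject_ids if s in shared]

    codes = []
    for c in clusterings:
        coding = _large_small_coding(c)
        lab = pd.Series(c.labels, index=c.subject_ids).reindex(ordered)
        codes.append(lab.map(lambda v: coding.get(int(v), None)))
    frame = pd.DataFrame(dict(zip(omic_names, codes)), index=ordered)
    outlier_mask = frame.isna().any(axis=1)
    n_excluded = int(outlier_mask.sum())
    if n_excluded:
        logger.info("%d shared subject(s) excluded as outliers in >=1 omic",
                    n_excluded)
    frame = frame[~outlier_mask]
    combination = frame.apply("-".join, axis=1)
    combination.name = "combination"

    all_l = "-".join(["L"] * len(omic_names))
    contrast = {"all_large": list(frame.index[combination == all_l])}
    for i, omic in enumerate(omic_names):
        pattern = ["L"] * len(omic_names)
        pattern[i] = "S"
        key = "-".join(pattern)
        contrast[f"small_{omic}_only"] = list(frame.index[combination == key])
    return IntegrationResult(
        subject_ids=list(frame.index),
        omics=list(omic_names),
        combination=combination,
        contrast_groups=contrast,
        n_excluded_outliers=n_excluded,
    )


def contrast_group_associations(
    result: IntegrationResult,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical associations of the derived contrast groups.

    Two analyses share one output table: the small-in-exactly-one groups
    against each other (multi-group tests), and the all-large group against
    every other combined subject (two-group tests); the ``contrast`` column
    says which analysis each row belongs to.
    """
    frames = []
    small_groups = {
        name: members
        for name, members in result.contrast_groups.items()
        if name != "all_large" and members
    }
    empty = [n for n, m in result.contrast_groups.items() if not m]
    for name in empty:
        logger.warning("contrast group %r is empty; excluded", name)
    if len(small_groups) >= 2:
        subjects, labels = [], []
        for name, members in small_groups.items():
            subjects.extend(members)
            labels.extend([name] * len(members))
        tab = test_clinical_associations(labels, clinical, subject_ids=subjects,
                                         alpha=alpha, seed=seed)
        tab.insert(0, "contrast", "small_in_exactly_one")
        frames.append(tab)
    all_large = set(result.contrast_groups.get("all_large", []))
    if all_large and len(all_large) < len(result.subject_ids):
        labels = ["all_large" if s in all_large else "rest"
                  for s in result.subject_ids]
        tab = test_clinical_associations(labels, clinical,
                                         subject_ids=result.subject_ids,
                                         alpha=alpha, seed=seed)
        tab.insert(0, "contrast", "all_large_vs_rest")
        frames.append(tab)
    if not frames:
        raise ValueError("need at least 2 non-empty contrast groups")
    table = pd.concat(frames, ignore_index=True)
    result.associations = table
    return table
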