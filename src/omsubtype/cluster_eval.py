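"""Cluster validity and sensitivity: silhouette, connectedness, normalized
Jaccard agreement, the gap statistic, and resampling stability.

Outlier points (label -1) are excluded from all internal validity
computations; they are reported separately by the clustering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .datatypes import OUTLIER_LABEL

logger = logging.getLogger("omsubtype")


@dataclass
class ValidityReport:
    overall: float
    per_cluster: dict  # label -> mean silhouette
    connectedness: float | None = None
    neighbors: int | None = None
    n_outliers: int = 0


def silhouette(points: np.ndarray, labels) -> ValidityReport:
    """Mean silhouette (b-a)/max(a,b) per cluster and overall.

    Singleton clusters contribute s=0, as do points where a=b=0 (identical
    coordinates). Outliers are excluded; with fewer than two clusters the
    silhouette is undefined and an error is raised.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = labels != OUTLIER_LABEL
    pts, labs = points[mask], labels[mask]
    uniq = np.unique(labs)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for fewer than 2 clusters")
    dist = cdist(pts, pts)
    s = np.zeros(len(pts))
    for i in range(len(pts)):
        own = labs == labs[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labs == other].mean() for other in uniq
                if other != labs[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_cluster = {int(c): float(s[labs == c].mean()) for c in uniq}
    return ValidityReport(
        overall=float(s.mean()),
        per_cluster=per_cluster,
        n_outliers=int((~mask).sum()),
    )


def connectedness(points: np.ndarray, labels, L: int = 10) -> float:
    """Neighborhood-purity score in [0, 1]; 1 means no point's L nearest
    neighbors cross cluster boundaries.

    The raw connectivity penalty sums 1/j whenever a point's j-th nearest
    non-outlier neighbor belongs to a different cluster; the score is
    1 - raw / (n * H_L). Distance ties are broken by point index. A single
    cluster scores 1.0 by construction.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    mask = labels != OUTLIER_LABEL
    pts, labs = points[mask], labels[mask]
    n = len(pts)
    if L >= n:
        raise ValueError(f"L={L} must be smaller than the {n} non-outlier points")
    if len(np.unique(labs)) == 1:
        return 1.0
    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :L]
    weights = 1.0 / np.arange(1, L + 1)
    crosses = labs[order] != labs[:, None]
    raw = float((crosses * weights).sum())
    h_l = float(weights.sum())
    return 1.0 - raw / (n * h_l)


def normalized_jaccard(A, B) -> float:
    """Jaccard overlap of two subject sets divided by its maximum achievable
    value given the two set sizes: (|A&B|/|A|B|) / (min/max)."""
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("normalized Jaccard undefined for empty sets")
    j = len(A & B) / len(A | B)
    j_max = min(len(A), len(B)) / max(len(A), len(B))
    return j / j_max


def _kmeans_labels(points, k, seed):
    if k == 1:
        return np.zeros(len(points), dtype=int)
    return KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(points)


def within_dispersion(points: np.ndarray, labels) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels, dtype=int)
    total = 0.0
    for c in np.unique(labels):
        cluster = points[labels == c]
        total += float(((cluster - cluster.mean(axis=0)) ** 2).sum())
    return total


def gap_statistic(
    points: np.ndarray,
    k_range=range(1, 11),
    B: int = 10,
    cluster_fn=None,
    seed: int = 0,
):
    """Tibshirani gap statistic; supports (and can prefer) k*=1.

    Gap(k) = mean_b log W_k(ref_b) - log W_k(data) with B uniform reference
    draws over the per-dimension bounding box. k* is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}. Returns (k*, curve table).
    """
    if B < 10:
        raise ValueError("need at least 10 reference datasets")
    points = np.asarray(points, dtype=float)
    cluster_fn = cluster_fn or _kmeans_labels
    k_range = sorted(int(k) for k in k_range)
    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    refs = [rng.uniform(lo, hi, size=points.shape) for _ in range(B)]

    def log_w(x, labels):
        w = within_dispersion(x, labels)
        if w <= 0:
            logger.warning("degenerate zero within-cluster dispersion")
            w = 1e-12
        return np.log(w)

    rows = []
    for k in k_range:
        lw_data = log_w(points, cluster_fn(points, k, seed))
        lw_refs = np.array(
            [log_w(r, cluster_fn(r, k, seed + 1 + b)) for b, r in enumerate(refs)]
        )
        gap = float(lw_refs.mean() - lw_data)
        s = float(lw_refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
        rows.append({"k": k, "log_w": lw_data, "gap": gap, "s": s})
    curve = pd.DataFrame(rows)
    k_star = k_range[-1]
    for i in range(len(k_range) - 1):
        if curve.loc[i, "gap"] >= curve.loc[i + 1, "gap"] - curve.loc[i + 1, "s"]:
            k_star = k_range[i]
            break
    return k_star, curve


def stability_resampling(
    points: np.ndarray,
    cluster_fn,
    R: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Mean normalized Jaccard of each original cluster against its best
    match across R reclustered subsamples.

    ``cluster_fn(points, seed) -> labels`` must be the full clustering
    routine under study. Replicates whose subsample cannot be clustered are
    skipped and counted in the returned series' attrs.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    points = np.asarray(points, dtype=float)
    n = len(points)
    original = np.asarray(cluster_fn(points, seed), dtype=int)
    orig_clusters = {
        int(c): set(np.flatnonzero(original == c))
        for c in np.unique(original) if c != OUTLIER_LABEL
    }
    rng = np.random.default_rng(seed)
    sums = {c: 0.0 for c in orig_clusters}
    counts = {c: 0 for c in orig_clusters}
    skipped = 0
    for r in range(R):
        idx = rng.choice(n, size=max(2, int(round(fraction * n))), replace=False)
        try:
            sub_labels = np.asarray(cluster_fn(points[idx], seed + 1 + r), dtype=int)
        except ValueError:
            skipped += 1
            continue
        sub_clusters = [
            {int(idx[i]) for i in np.flatnonzero(sub_labels == c)}
            for c in np.unique(sub_labels) if c != OUTLIER_LABEL
        ]
        if not sub_clusters:
            skipped += 1
            continue
        idx_set = set(int(i) for i in idx)
        for c, members in orig_clusters.items():
            restricted = members & idx_set
            if not restricted:
                continue
            best = max(
                normalized_jaccard(restricted, sc) for sc in sub_clusters
            )
            sums[c] += best
            counts[c] += 1
    result = pd.Series(
        {c: (sums[c] / counts[c] if counts[c] else np.nan) for c in orig_clusters},
        name="stability",
    )
    result.attrs["skipped_replicates"] = skipped
    return result
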