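"""Projected (subspace) clustering via the MineClus/DOC model.

A projected cluster is a medoid p, a set of relevant dimensions D, and the
points lying within a half-width w of p on every dimension in D. Candidate
clusters are scored by the quality function mu(a, b) = a * (1/beta)^b, which
trades cluster size a against subspace dimensionality b. Clusters are mined
greedily: the best cluster over candidate medoids is extracted, its members
removed, and the search repeated; points never assigned are outliers (-1).

For embeddings of width m <= 16 the optimal dimension subset per medoid is
found exactly by a subset-lattice sweep (zeta transform over point
bitmasks); for wider spaces an equivalent branch-and-bound itemset search is
used. A k-means baseline and the systematic (w, k) selection routine used by
the pipeline live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import cluster_eval
from .datatypes import OUTLIER_LABEL, Clustering, ProjectedCluster

logger = logging.getLogger("omsubtype")

EXHAUSTIVE_MAX_DIMS = 16
MEDOID_SAMPLE_MAX = 2000
MINING_NODE_BUDGET = 2048  # per-medoid search budget for wide embeddings


@dataclass
class MineClusParams:
    """w: per-dimension half-width; beta: dimension reward in (0,1);
    alpha: minimum support as a fraction of the remaining points."""

    w: float
    beta: float = 0.25
    alpha: float = 0.10
    k_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0,1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0,1]")


def mu_quality(a: float, b: float, beta: float) -> float:
    """DOC quality mu(a, b) = a * (1/beta)^b."""
    if a < 0 or b < 0:
        raise ValueError("a and b must be non-negative")
    return a * (1.0 / beta) ** b


@lru_cache(maxsize=8)
def _popcounts(m: int) -> np.ndarray:
    return np.array([bin(i).count("1") for i in range(1 << m)], dtype=np.int64)


def _bit_tuple(mask: int) -> tuple:
    return tuple(d for d in range(mask.bit_length()) if mask >> d & 1)


def best_cluster_for_medoid(points: np.ndarray, medoid_index: int,
                            params: MineClusParams):
    """Optimal (members, dims, quality) for one medoid, or None.

    Each point q is encoded as the itemset {d : |q_d - p_d| <= w}; the best
    dimension subset D maximizes mu(|C_D|, |D|) over subsets supported by at
    least alpha*n points, where C_D is the set of points whose itemset
    contains D. Ties prefer larger |D|, then the lexicographically smallest D.
    """
    points = np.asarray(points, dtype=float)
    n, m = points.shape
    close = np.abs(points - points[medoid_index]) <= params.w
    min_support = params.alpha * n
    if m <= EXHAUSTIVE_MAX_DIMS:
        best = _best_subset_exhaustive(close, min_support, params.beta)
    else:
        best = _best_subset_mining(close, min_support, params.beta,
                                   max_nodes=MINING_NODE_BUDGET)
    if best is None:
        return None
    quality, mask = best
    members = np.flatnonzero((_masks_of(close) & mask) == mask)
    return members, _bit_tuple(mask), quality


def _masks_of(close: np.ndarray) -> np.ndarray:
    m = close.shape[1]
    powers = (1 << np.arange(m, dtype=np.int64))
    return close.astype(np.int64) @ powers


def _best_subset_exhaustive(close: np.ndarray, min_support: float, beta: float):
    n, m = close.shape
    masks = _masks_of(close)
    f = np.bincount(masks, minlength=1 << m).astype(np.int64)
    # zeta transform: f[D] <- number of points whose itemset is a superset of D
    indices = np.arange(1 << m)
    for b in range(m):
        bit = 1 << b
        lower = indices[(indices & bit) == 0]
        f[lower] += f[lower | bit]
    pc = _popcounts(m)
    quality = f * (1.0 / beta) ** pc
    feasible = (f >= min_support) & (indices > 0)
    if not feasible.any():
        return None
    quality = np.where(feasible, quality, -np.inf)
    qmax = quality.max()
    ties = np.flatnonzero(quality == qmax)
    depth = pc[ties]
    ties = ties[depth == depth.max()]
    if len(ties) > 1:
        mask = min((int(t) for t in ties), key=_bit_tuple)
    else:
        mask = int(ties[0])
    return qmax, mask


def _best_subset_mining(close: np.ndarray, min_support: float, beta: float,
                        max_nodes: int | None = None):
    """Branch-and-bound search over frequent dimension itemsets.

    Items are ordered by support (descending); a branch is pruned when even
    extending by every remaining item cannot beat the incumbent quality.
    Exact when ``max_nodes`` is None; with a node budget (used for wide
    embeddings, where the frequent-itemset lattice is astronomically large)
    the search is best-effort but still visits the greedy support-ordered
    branch first.
    """
    n, m = close.shape
    supports = close.sum(axis=0)
    order = np.argsort(-supports, kind="stable")
    items = [int(d) for d in order if supports[d] >= min_support]
    inv_beta = 1.0 / beta
    best = {"q": -np.inf, "pc": 0, "dims": None}

    def consider(count, dims):
        q = count * inv_beta ** len(dims)
        key = tuple(sorted(dims))
        if (q > best["q"]
                or (q == best["q"] and len(dims) > best["pc"])
                or (q == best["q"] and len(dims) == best["pc"]
                    and (best["dims"] is None or key < best["dims"]))):
            best.update(q=q, pc=len(dims), dims=key)

    budget = [max_nodes if max_nodes is not None else -1]

    def dfs(start, dims, rows, count):
        for pos in range(start, len(items)):
            if budget[0] == 0:
                return
            budget[0] -= 1
            d = items[pos]
            new_rows = rows & close[:, d]
            cnt = int(new_rows.sum())
            if cnt < min_support:
                continue
            new_dims = dims + [d]
            consider(cnt, new_dims)
            # a descendant can add at most the items still ahead of pos,
            # with support never exceeding cnt; prune when even that bound
            # cannot match the incumbent (ties kept: deeper sets win them)
            bound = cnt * inv_beta ** (len(new_dims) + len(items) - pos - 1)
            if bound >= best["q"]:
                dfs(pos + 1, new_dims, new_rows, cnt)

    dfs(0, [], np.ones(n, dtype=bool), n)
    if best["dims"] is None:
        return None
    mask = 0
    for d in best["dims"]:
        mask |= 1 << d
    return best["q"], mask


def mineclus_cluster(points: np.ndarray, params: MineClusParams) -> Clustering:
    """Greedy iterative mining of up to k_max projected clusters.

    Candidate medoids are all remaining points up to 2000, beyond that a
    seeded random sample of 2000. Unassigned points get the outlier label.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(params.seed)
    labels = np.full(n, OUTLIER_LABEL, dtype=int)
    remaining = np.arange(n)
    clusters = []
    while len(clusters) < params.k_max and len(remaining) >= 2:
        sub = points[remaining]
        if len(remaining) > MEDOID_SAMPLE_MAX:
            medoids = np.sort(rng.choice(len(remaining), size=MEDOID_SAMPLE_MAX,
                                         replace=False))
        else:
            medoids = np.arange(len(remaining))
        best = None
        for i in medoids:
            res = best_cluster_for_medoid(sub, int(i), params)
            if res is None:
                continue
            members, dims, quality = res
            key = (quality, len(dims), tuple(-d for d in dims))
            if best is None or key > best[0]:
                best = (key, members, dims, quality, int(i))
        if best is None:
            break
        _, members, dims, quality, medoid_i = best
        members, medoid_i, quality = _recenter(sub, members, dims, medoid_i,
                                               params)
        label = len(clusters)
        global_members = remaining[members]
        labels[global_members] = label
        clusters.append(
            ProjectedCluster(
                members=global_members,
                dims=tuple(dims),
                medoid=points[remaining[medoid_i]].copy(),
                quality=quality,
            )
        )
        keep = np.ones(len(remaining), dtype=bool)
        keep[members] = False
        remaining = remaining[keep]
    return Clustering(
        labels=labels,
        clusters=clusters,
        params={"method": "mineclus", "w": params.w, "beta": params.beta,
                "alpha": params.alpha, "k_max": params.k_max, "seed": params.seed},
    )


def _recenter(points, members, dims, medoid_i, params):
    """Re-anchor a mined cluster on its most central member.

    A randomly drawn medoid can sit near one face of the cluster's box and
    miss members on the far side; one re-anchoring pass picks the member
    closest to the box midrange on the relevant dimensions and re-collects
    the points within w of it. The anchor stays an actual data point, so the
    width invariant is untouched.
    """
    dims = list(dims)
    for _ in range(2):
        box = points[np.ix_(members, dims)]
        mid = (box.min(axis=0) + box.max(axis=0)) / 2.0
        centrality = np.abs(box - mid).max(axis=1)
        new_medoid = int(members[int(np.argmin(centrality))])
        new_members = np.flatnonzero(
            (np.abs(points[:, dims] - points[new_medoid, dims])
             <= params.w).all(axis=1)
        )
        if new_medoid == medoid_i and len(new_members) == len(members) \
                and np.array_equal(new_members, members):
            break
        members, medoid_i = new_members, new_medoid
    quality = mu_quality(len(members), len(dims), params.beta)
    return members, medoid_i, quality


def truncate_clustering(clustering: Clustering, k: int) -> Clustering:
    """First k greedily mined clusters; later members become outliers.

    Identical to re-running the miner with k_max=k, because each greedy
    iteration is independent of k_max.
    """
    if k >= clustering.n_clusters:
        return clustering
    labels = clustering.labels.copy()
    labels[labels >= k] = OUTLIER_LABEL
    return Clustering(
        labels=labels,
        clusters=clustering.clusters[:k],
        params={**clustering.params, "k_max": k},
        subject_ids=clustering.subject_ids,
    )


def kmeans_baseline(points: np.ndarray, k: int, seed: int = 0) -> Clustering:
    """Seeded k-means++ Lloyd clustering, 10 restarts, no outliers.

    All dimensions are relevant; cluster labels are ordered by decreasing
    size and medoids are the points nearest each centroid.
    """
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(points):
        raise ValueError(f"k={k} exceeds n={len(points)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(points)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    m = points.shape[1]
    clusters = []
    for new_label, old in enumerate(order):
        members = np.flatnonzero(labels == new_label)
        center = km.cluster_centers_[old]
        if len(members):
            medoid = points[members[np.argmin(
                ((points[members] - center) ** 2).sum(axis=1))]].copy()
        else:  # k-means can leave a cluster empty on degenerate data
            medoid = center.copy()
        clusters.append(
            ProjectedCluster(members=members, dims=tuple(range(m)),
                             medoid=medoid, quality=float("nan"))
        )
    return Clustering(labels=labels, clusters=clusters,
                      params={"method": "kmeans", "k": k, "seed": seed})


def default_w_grid(points: np.ndarray, seed: int = 0, n_pairs: int = 1000):
    """Quantiles of per-dimension absolute differences between random point
    pairs: the deciles 10%..90% plus the 95% and 99% tails.

    The upper-tail widths matter when embedding dimensions have very
    different scales: a box must be wide enough to cover a whole cluster on
    its largest-scale dimension, which the deciles alone can miss.
    """
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(points)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    diffs = np.abs(points[i] - points[j]).ravel()
    qs = np.concatenate([np.arange(0.1, 0.91, 0.1), [0.95, 0.99]])
    grid = np.quantile(diffs, qs)
    grid = sorted({float(w) for w in grid if w > 0})
    if not grid:
        raise ValueError("degenerate data: all pairwise differences are zero")
    return grid


@dataclass
class SelectionResult:
    chosen: Clustering | None
    table: pd.DataFrame
    k1_verdict: bool

    @property
    def chosen_row(self):
        hits = self.table[self.table["chosen"]]
        return None if hits.empty else hits.iloc[0]


def select_params(
    points: np.ndarray,
    w_grid=None,
    k_range=range(2, 11),
    min_small_silhouette: float = 0.10,
    seed: int = 0,
    beta: float = 0.25,
    alpha: float = 0.10,
    neighbors: int = 10,
    max_outlier_fraction: float = 0.10,
) -> SelectionResult:
    """Systematic (w, k) search with a small-cluster silhouette constraint.

    Every (w, k) candidate is mined, scored by overall silhouette and
    connectedness (outliers excluded); candidates whose smallest cluster
    silhouette is <= the constraint are discarded whenever any candidate
    passes it. Selection maximizes overall silhouette with ties broken by
    higher connectedness, then smaller k, then smaller w. If no candidate
    yields two clusters the verdict is k=1.

    Because the silhouette ignores outliers, a candidate that labels most of
    the cohort as outliers can trivially dominate it; candidates declaring
    more than ``max_outlier_fraction`` of subjects outliers are therefore
    ineligible whenever any candidate stays within the budget. A subtyping
    that discards most subjects is not a subtyping.
    """
    points = np.asarray(points, dtype=float)
    k_range = sorted(int(k) for k in k_range)
    if w_grid is None:
        w_grid = default_w_grid(points, seed=seed)
    rows = []
    candidates = {}
    for w in w_grid:
        params = MineClusParams(w=float(w), beta=beta, alpha=alpha,
                                k_max=max(k_range), seed=seed)
        full = mineclus_cluster(points, params)
        for k in k_range:
            clustering = truncate_clustering(full, k)
            row = {
                "w": float(w), "k": k,
                "n_clusters": clustering.n_clusters,
                "n_outliers": clustering.n_outliers,
                "sizes": ";".join(str(s) for s in clustering.sizes()),
                "silhouette": np.nan, "min_cluster_silhouette": np.nan,
                "connectedness": np.nan,
            }
            if clustering.n_clusters >= 2:
                report = cluster_eval.silhouette(points, clustering.labels)
                row["silhouette"] = report.overall
                row["min_cluster_silhouette"] = min(report.per_cluster.values())
                row["connectedness"] = cluster_eval.connectedness(
                    points, clustering.labels, L=neighbors
                )
                clustering.metrics = {
                    "silhouette": row["silhouette"],
                    "per_cluster_silhouette": report.per_cluster,
                    "connectedness": row["connectedness"],
                }
            candidates[(float(w), k)] = clustering
            rows.append(row)
    table = pd.DataFrame(rows)
    eligible = table[table["silhouette"].notna()]
    if eligible.empty:
        logger.warning("no (w, k) candidate produced >= 2 clusters: k=1 verdict")
        table["chosen"] = False
        return SelectionResult(chosen=None, table=table, k1_verdict=True)
    outlier_budget = max_outlier_fraction * len(points)
    within_budget = eligible[eligible["n_outliers"] <= outlier_budget]
    if not within_budget.empty:
        eligible = within_budget
    passing = eligible[eligible["min_cluster_silhouette"] > min_small_silhouette]
    pool = passing if not passing.empty else eligible
    ranked = pool.sort_values(
        by=["silhouette", "connectedness", "k", "w"],
        ascending=[False, False, True, True],
        kind="stable",
    )
    best = ranked.iloc[0]
    table["chosen"] = (table["w"] == best["w"]) & (table["k"] == best["k"])
    chosen = candidates[(float(best["w"]), int(best["k"]))]
    return SelectionResult(chosen=chosen, table=table, k1_verdict=False)
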