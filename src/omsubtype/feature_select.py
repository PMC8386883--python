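"""Subtype-discriminating feature selection by SVM recursive feature
elimination (SVM-RFE).

A linear soft-margin SVM (C=1, class weights balanced for the 85/15 subtype
imbalance) is fitted repeatedly; each iteration removes the features with the
smallest squared coefficients (10% of those remaining by default) and the
final ranking is the reverse removal order. The selected set size is the
smallest prefix within one standard error of the best cross-validated
f1-score; f1 is computed for the smaller (positive) class. Cumulative
per-prefix f1 scores and a relaxed enrichment set round out the report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import OUTLIER_LABEL, OmicsMatrix

logger = logging.getLogger("omsubtype")

RELAXED_FLOOR = 20  # minimum feature count for meaningful enrichment


@dataclass
class FeatureRanking:
    features: list  # rank 1 first
    cumulative_f1: list
    chosen_size: int
    relaxed: list

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "cumulative_f1": self.cumulative_f1,
                "in_optimal_set": np.arange(len(self.features)) < self.chosen_size,
            }
        )


def _svm() -> SVC:
    return SVC(kernel="linear", C=1.0, class_weight="balanced")


def _prepare(X, labels):
    if isinstance(X, OmicsMatrix):
        values, features = X.values, list(X.feature_ids)
    else:
        values = np.asarray(X, dtype=float)
        features = list(range(values.shape[1]))
    labels = np.asarray(labels)
    keep = labels != OUTLIER_LABEL
    values, labels = values[keep], labels[keep]
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if counts.min() < 3:
        raise ValueError("each class needs at least 3 members")
    # the smaller subtype is the positive class for f1
    positive = classes[np.argmin(counts)]
    y = (labels == positive).astype(int)
    return values, y, features


def _rfe_order(values: np.ndarray, y: np.ndarray, step) -> list:
    """Column indices in removal order (first removed = least discriminating)."""
    remaining = list(range(values.shape[1]))
    removal_order = []
    while remaining:
        if len(remaining) == 1:
            removal_order.extend(remaining)
            break
        svm = _svm().fit(values[:, remaining], y)
        weight2 = np.asarray(svm.coef_).ravel() ** 2
        n_remove = step if step is not None else max(1, math.ceil(0.10 * len(remaining)))
        n_remove = min(n_remove, len(remaining) - 1)
        # weakest first; ties broken by column index for determinism
        order = np.lexsort((np.arange(len(remaining)), weight2))
        drop = sorted(order[:n_remove], reverse=True)
        batch = []
        for pos in drop:
            batch.append(remaining.pop(pos))
        # within a batch, weaker features are removed earlier
        batch_w = {f: w for f, w in zip(batch, weight2[drop])}
        removal_order.extend(sorted(batch, key=lambda f: (batch_w[f], f)))
        if len(remaining) == 1:
            removal_order.extend(remaining)
            break
    return removal_order


def svmrfe_rank(X, labels, step: int | None = None) -> list:
    """Feature IDs ranked most-discriminating first (reverse removal order)."""
    values, y, features = _prepare(X, labels)
    if step is not None and step < 1:
        raise ValueError("step must be >= 1")
    order = _rfe_order(values, y, step)
    return [features[i] for i in reversed(order)]


def _prefix_sizes(p: int, step) -> list:
    """Candidate set sizes along the RFE path (remaining counts), ascending."""
    sizes = []
    remaining = p
    while remaining > 1:
        sizes.append(remaining)
        n_remove = step if step is not None else max(1, math.ceil(0.10 * remaining))
        remaining -= min(n_remove, remaining - 1)
    sizes.append(1)
    return sorted(sizes)


def choose_feature_count(
    X, labels, folds: int = 5, seed: int = 0, step: int | None = None
) -> int:
    """Cross-validated size selection along the RFE path.

    Within each stratified fold the RFE ranking is recomputed on the training
    split and every candidate prefix size is scored by f1 on the held-out
    split; the chosen size is the smallest one within one standard error of
    the maximum mean f1.
    """
    values, y, _ = _prepare(X, labels)
    if np.bincount(y).min() < folds:
        raise ValueError(f"cannot stratify {folds} folds: a class has fewer members")
    sizes = _prefix_sizes(values.shape[1], step)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros((folds, len(sizes)))
    for f, (tr, te) in enumerate(skf.split(values, y)):
        order = _rfe_order(values[tr], y[tr], step)
        ranking = list(reversed(order))
        for s_i, size in enumerate(sizes):
            cols = ranking[:size]
            svm = _svm().fit(values[np.ix_(tr, cols)], y[tr])
            scores[f, s_i] = f1_score(y[te], svm.predict(values[np.ix_(te, cols)]))
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / math.sqrt(folds)
    best = int(np.argmax(mean))
    threshold = mean[best] - se[best]
    for s_i, size in enumerate(sizes):
        if mean[s_i] >= threshold:
            return size
    return sizes[best]


def cumulative_f1(X, labels, ranking: list, seed: int = 0, folds: int = 5) -> list:
    """Cross-validated f1 of an SVM restricted to each prefix of the ranking."""
    values, y, features = _prepare(X, labels)
    index = {f: i for i, f in enumerate(features)}
    cols = [index[f] for f in ranking]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(values, y))
    out = []
    for size in range(1, len(cols) + 1):
        sub = values[:, cols[:size]]
        fold_scores = []
        for tr, te in splits:
            svm = _svm().fit(sub[tr], y[tr])
            fold_scores.append(f1_score(y[te], svm.predict(sub[te])))
        out.append(float(np.mean(fold_scores)))
    return out


def relaxed_set(
    ranking: list,
    cumulative: list,
    threshold: float | None = None,
    floor: int = RELAXED_FLOOR,
) -> list:
    """Expanded feature list for enrichment.

    Default rule: keep every prefix feature whose cumulative f1 exceeds the
    mean cumulative f1 plus one percentage point; an absolute threshold can
    be supplied instead. The set is padded with the next best-ranked features
    up to the floor (default 20) so enrichment has enough members.
    """
    cumulative = list(cumulative)
    if threshold is None:
        threshold = float(np.mean(cumulative)) + 0.01
    selected = [f for f, score in zip(ranking, cumulative) if score > threshold]
    if len(selected) < floor:
        for f in ranking:
            if len(selected) >= floor:
                break
            if f not in selected:
                selected.append(f)
    if not selected:
        logger.warning("relaxed rule selected no features and the floor is 0")
    return selected


def select_features(
    X, labels, seed: int = 0, folds: int = 5, step: int | None = None
) -> FeatureRanking:
    """Full feature-selection step: rank, choose size, score prefixes, relax."""
    ranking = svmrfe_rank(X, labels, step=step)
    chosen = choose_feature_count(X, labels, folds=folds, seed=seed, step=step)
    cumulative = cumulative_f1(X, labels, ranking, seed=seed, folds=folds)
    relaxed = relaxed_set(ranking, cumulative)
    return FeatureRanking(
        features=ranking,
        cumulative_f1=cumulative,
        chosen_size=chosen,
        relaxed=relaxed,
    )
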