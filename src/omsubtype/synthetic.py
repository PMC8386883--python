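"""Synthetic multi-omics data with known ground truth.

The generator emulates the structure the subtyping pipeline is built for:
partially overlapping subject sets across 2-3 omic layers, one large
(~85-90%) and one small (~10-15%) planted subtype living in a subset of the
dimensions of a shared low-dimensional latent space, cell-composition
confounding with known linear effects, clinical variables of mixed type with
known subtype associations, and pure-noise features that the covariate filter
must remove.

Latent subject coordinates are uniform (box-shaped clusters, the generative
model projected clustering assumes); the small subtype is translated by
``delta`` latent standard deviations on the dimensions carrying the signal.
Each informative feature loads on one signal-bearing and one background
latent dimension (pathway-like sparsity) and is passed through an
elementwise tanh before an output gain, so the omic-to-latent map is
nonlinear — the translated subtype saturates the tanh into a compact,
well-separated cloud while the large subtype stays in the quasi-linear
regime — and a nonlinear embedding can out-reconstruct a same-width linear
one. All randomness flows from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ClinicalVariable, OmicsMatrix

logger = logging.getLogger("omsubtype")

OMIC_NAMES = ("transcriptomics", "proteomics", "metabolomics")
CELL_VARS = (
    "hemoglobin",
    "neutrophil_pct",
    "lymphocyte_pct",
    "eosinophil_pct",
    "monocyte_pct",
    "wbc_count",
)


@dataclass
class SimConfig:
    """Study conditions for the default synthetic cohort.

    Defaults: three omic layers of 500 subjects each sharing a 400-subject
    core, a 6-dimensional uniform latent space with the subtype translating
    dimensions (0, 1, 2) by ``delta`` latent standard deviations, a 12.5%
    small subtype, and per omic 120 informative features (one signal and one
    background loading each) plus an equal number of pure-noise features.
    The default ``delta`` is large on the latent scale but reaches features
    only through tanh saturation and small loadings, yielding feature-level
    subtype effects of roughly 2-4 standard deviations.
    """

    n_omics: int = 3
    n_per_omic: int = 500
    n_shared: int = 400
    latent_dim: int = 6
    latent_dims_used: tuple = (0, 1, 2)
    delta: float = 12.0
    small_fraction: float = 0.125
    n_informative: int = 120
    noise_feature_fraction: float = 0.5
    signal_loading: float = 0.15
    background_loading: float = 0.05
    feature_gain: float = 3.0
    noise_sd: float = 0.5
    cell_effect_scale: float = 0.5
    cell_label_assoc: float = 0.5
    filter_var_noise_sd: float = 0.3
    n_assoc_continuous: int = 2
    n_assoc_binary: int = 2
    assoc_effect: float = 1.0
    n_null_clinical: int = 8
    clinical_missing_rate: float = 0.02
    check_recovery: bool = False

    def __post_init__(self) -> None:
        if self.n_omics not in (1, 2, 3):
            raise ValueError("n_omics must be 1, 2 or 3")
        for name in ("n_per_omic", "n_shared", "latent_dim", "n_informative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_shared > self.n_per_omic:
            raise ValueError("shared subjects cannot exceed each omic's n")
        if not 0.0 <= self.small_fraction < 0.5:
            raise ValueError("small_fraction must lie in [0, 0.5)")
        if any(d >= self.latent_dim for d in self.latent_dims_used):
            raise ValueError("latent_dims_used outside latent space")

    @property
    def n_noise_features(self) -> int:
        frac = self.noise_feature_fraction
        return int(round(self.n_informative * frac / max(1e-12, 1.0 - frac)))

    @property
    def n_pool(self) -> int:
        return self.n_shared + self.n_omics * (self.n_per_omic - self.n_shared)


@dataclass
class GroundTruth:
    true_label: pd.Series  # "large" / "small" per pool subject
    informative_feature_ids: dict  # omic -> list of non-noise feature IDs
    subtype_feature_ids: dict  # omic -> features loading on shifted dims
    latent_dims_used: tuple
    clinical_assoc_vars: list
    effects: dict

    def labels_for(self, subject_ids) -> np.ndarray:
        return self.true_label.reindex(subject_ids).to_numpy()


def generate_multiomics(config: SimConfig, seed: int):
    """Draw one synthetic cohort; returns (omics list, clinical, truth)."""
    rng = np.random.default_rng(seed)
    if config.delta == 0 and config.check_recovery:
        logger.warning("delta=0: no recoverable subtype structure was planted")

    n_pool = config.n_pool
    q = config.latent_dim
    subjects = [f"S{i:04d}" for i in range(n_pool)]
    n_small = int(round(config.small_fraction * n_pool))
    small = np.zeros(n_pool, dtype=bool)
    small[rng.permutation(n_pool)[:n_small]] = True
    y = small.astype(float)

    # uniform latent coordinates (unit variance); box-shaped clusters
    half_range = np.sqrt(3.0)
    z = rng.uniform(-half_range, half_range, size=(n_pool, q))
    for d in config.latent_dims_used:
        z[:, d] += config.delta * y

    # cell composition, correlated with the subtype at configurable strength
    cells = rng.standard_normal((n_pool, len(CELL_VARS)))
    cells += config.cell_label_assoc * y[:, None]

    # subject sets: a shared core plus per-omic unique blocks
    omic_subject_idx = []
    offset = config.n_shared
    for _ in range(config.n_omics):
        unique = np.arange(offset, offset + config.n_per_omic - config.n_shared)
        omic_subject_idx.append(np.concatenate([np.arange(config.n_shared), unique]))
        offset += config.n_per_omic - config.n_shared

    omics = []
    informative_ids: dict = {}
    subtype_ids: dict = {}
    for o in range(config.n_omics):
        name = OMIC_NAMES[o]
        idx = omic_subject_idx[o]
        p_inf, p_noise = config.n_informative, config.n_noise_features

        # one signal-bearing and one background loading per feature
        used = list(config.latent_dims_used)
        rest = [d for d in range(q) if d not in used] or used
        W = np.zeros((q, p_inf))
        signal_dim = rng.choice(used, size=p_inf)
        background_dim = rng.choice(rest, size=p_inf)
        cols = np.arange(p_inf)
        W[signal_dim, cols] = rng.choice([-1.0, 1.0], p_inf) * config.signal_loading
        W[background_dim, cols] += (rng.choice([-1.0, 1.0], p_inf)
                                    * config.background_loading)

        X_inf = config.feature_gain * np.tanh(z[idx] @ W)
        X_inf += config.noise_sd * rng.standard_normal(X_inf.shape)
        # known linear cell-composition effects
        gamma = rng.standard_normal((len(CELL_VARS), p_inf))
        gamma *= config.cell_effect_scale / np.sqrt(len(CELL_VARS))
        X_inf += cells[idx] @ gamma

        X_noise = rng.standard_normal((len(idx), p_noise))

        inf_ids = [f"{name}_f{j:04d}" for j in range(p_inf)]
        noise_ids = [f"{name}_f{p_inf + j:04d}" for j in range(p_noise)]
        # every informative feature loads on a shifted dimension
        subtype_ids[name] = list(inf_ids)
        informative_ids[name] = inf_ids
        omics.append(
            OmicsMatrix(
                name,
                [subjects[i] for i in idx],
                inf_ids + noise_ids,
                np.hstack([X_inf, X_noise]),
            )
        )

    clinical, assoc_vars = _make_clinical(config, rng, subjects, z, y, cells)
    truth = GroundTruth(
        true_label=pd.Series(np.where(small, "small", "large"), index=subjects),
        informative_feature_ids=informative_ids,
        subtype_feature_ids=subtype_ids,
        latent_dims_used=tuple(config.latent_dims_used),
        clinical_assoc_vars=assoc_vars,
        effects={
            "delta": config.delta,
            "assoc_effect": config.assoc_effect,
            "cell_label_assoc": config.cell_label_assoc,
        },
    )
    return omics, clinical, truth


def _make_clinical(config, rng, subjects, z, y, cells):
    n = len(subjects)
    variables = []
    for j, cv in enumerate(CELL_VARS):
        variables.append(
            ClinicalVariable(cv, "continuous", {"cell_count"},
                             pd.Series(cells[:, j], index=subjects))
        )
    # filter variables: one noisy readout per latent dimension
    for d in range(config.latent_dim):
        zd = z[:, d] / max(1.0, z[:, d].std())
        vals = zd + config.filter_var_noise_sd * rng.standard_normal(n)
        variables.append(
            ClinicalVariable(f"lat{d}", "continuous", {"filter", "test"},
                             pd.Series(vals, index=subjects))
        )
    assoc_vars = []
    for j in range(config.n_assoc_continuous):
        vals = config.assoc_effect * y + rng.standard_normal(n)
        vals = _sprinkle_missing(vals, config.clinical_missing_rate, rng)
        nm = f"assoc_cont{j}"
        assoc_vars.append(nm)
        variables.append(
            ClinicalVariable(nm, "continuous", {"test"}, pd.Series(vals,
                                                                   index=subjects))
        )
    for j in range(config.n_assoc_binary):
        p = np.where(y > 0, 0.6, 0.2)
        vals = np.where(rng.random(n) < p, "yes", "no").astype(object)
        miss = rng.random(n) < config.clinical_missing_rate
        vals[miss] = np.nan
        nm = f"assoc_bin{j}"
        assoc_vars.append(nm)
        variables.append(
            ClinicalVariable(nm, "binary", {"test"}, pd.Series(vals, index=subjects))
        )
    for j in range(config.n_null_clinical):
        if j % 2 == 0:
            vals = _sprinkle_missing(rng.standard_normal(n),
                                     config.clinical_missing_rate, rng)
            kind = "continuous"
        else:
            vals = np.where(rng.random(n) < 0.5, "a", "b").astype(object)
            kind = "binary"
        variables.append(
            ClinicalVariable(f"null{j}", kind, {"test"},
                             pd.Series(vals, index=subjects))
        )
    return ClinicalTable(list(subjects), variables), assoc_vars


def _sprinkle_missing(vals, rate, rng):
    vals = np.asarray(vals, dtype=float).copy()
    vals[rng.random(len(vals)) < rate] = np.nan
    return vals


def schema_of(table: ClinicalTable) -> dict:
    """Role/kind declarations matching a generated clinical table."""
    return {v.name: (v.kind, set(v.roles)) for v in table.variables}


def generate_projected_clusters(
    n: int,
    m: int,
    spec: list,
    noise_n: int,
    seed: int,
    domain: tuple = (0.0, 100.0),
):
    """Planted projected clusters for exercising the subspace miner.

    ``spec`` is a list of ``(size, dim_subset, center, half_width)``; each
    cluster's points lie within half_width of its center on its relevant
    dimensions and are uniform over the domain elsewhere. ``noise_n`` points
    are uniform on all dimensions. ``n`` must equal the total point count.

    Returns (points, labels, dim_subsets) with noise labelled -1.
    """
    total = sum(size for size, *_ in spec) + noise_n
    if n != total:
        raise ValueError(f"n={n} but spec plants {total} points")
    lo, hi = domain
    rng = np.random.default_rng(seed)
    blocks, labels, dim_subsets = [], [], []
    for k, (size, dims, center, hw) in enumerate(spec):
        dims = tuple(sorted(dims))
        if hw <= 0:
            raise ValueError("half-width must be positive")
        if any(d < 0 or d >= m for d in dims):
            raise ValueError(f"dimension subset {dims} outside 0..{m - 1}")
        center = np.broadcast_to(np.asarray(center, dtype=float), (len(dims),))
        pts = rng.uniform(lo, hi, size=(size, m))
        for d, c in zip(dims, center):
            pts[:, d] = rng.uniform(c - hw, c + hw, size=size)
        blocks.append(pts)
        labels.extend([k] * size)
        dim_subsets.append(dims)
    for a in range(len(spec)):
        for b in range(a + 1, len(spec)):
            shared = set(dim_subsets[a]) & set(dim_subsets[b])
            if shared and _boxes_overlap(spec[a], spec[b], shared):
                logger.warning("planted clusters %d and %d overlap", a, b)
    if noise_n:
        blocks.append(rng.uniform(lo, hi, size=(noise_n, m)))
        labels.extend([-1] * noise_n)
    return np.vstack(blocks), np.asarray(labels), dim_subsets


def _boxes_overlap(spec_a, spec_b, shared) -> bool:
    _, dims_a, ca, ha = spec_a
    _, dims_b, cb, hb = spec_b
    ca = dict(zip(sorted(dims_a), np.broadcast_to(np.asarray(ca, float),
                                                  (len(dims_a),))))
    cb = dict(zip(sorted(dims_b), np.broadcast_to(np.asarray(cb, float),
                                                  (len(dims_b),))))
    return all(abs(ca[d] - cb[d]) <= ha + hb for d in shared)


def tanh_manifold(n: int, q: int, p: int, noise_sd: float, seed: int,
                  scale: float = 2.0) -> np.ndarray:
    """Points on a q-dimensional tanh-bent manifold embedded in p dimensions.

    ``scale`` sets the standard deviation of the pre-activation, i.e. how far
    into tanh saturation the manifold bends; 2.0 is strongly nonlinear.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, q))
    W = rng.standard_normal((q, p)) * (scale / np.sqrt(q))
    return np.tanh(z @ W) + noise_sd * rng.standard_normal((n, p))
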