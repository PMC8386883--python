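"""Embeddings: PCA and a seeded autoencoder, elbow-based width selection,
and reconstruction-error comparison between the two reducers.

The autoencoder is a symmetric multilayer perceptron (p -> h -> m -> h -> p,
tanh hidden activations, linear bottleneck and output) trained with Adam on
mean squared reconstruction error. A randomly chosen 10% of subjects is held
out; the model is flagged as overfit when the relative train/test error gap
exceeds 5%. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import OmicsMatrix

logger = logging.getLogger("omsubtype")

OVERFIT_GAP = 0.05  # relative train/test error difference


@dataclass
class Embedding:
    method: str  # "pca" | "autoencoder" | "concat"
    subject_ids: list
    m: int
    coordinates: np.ndarray  # n x m, row-aligned to subject_ids
    reducer: object | None = None  # exposes encode/decode
    diagnostics: dict = field(default_factory=dict)

    @property
    def overfit(self) -> bool:
        return bool(self.diagnostics.get("overfit", False))


def overfit_flag(train_mse: float, test_mse: float) -> bool:
    """True when train and test error differ by more than 5% (relative)."""
    if train_mse <= 0:
        return test_mse > 0
    return abs(test_mse - train_mse) / train_mse > OVERFIT_GAP + 1e-12


class _PCAReducer:
    def __init__(self, mean: np.ndarray, components: np.ndarray):
        self.mean = mean
        self.components = components  # m x p

    def encode(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T

    def decode(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components + self.mean

    @property
    def n_features(self) -> int:
        return self.components.shape[1]


def fit_pca(X: OmicsMatrix, m: int) -> Embedding:
    """Top-m principal scores with a fixed sign convention.

    Signs are chosen so each component's largest-magnitude loading is
    positive, making the embedding reproducible across BLAS builds.
    """
    n, p = X.values.shape
    if not 1 <= m <= min(n, p):
        raise ValueError(f"m={m} outside [1, {min(n, p)}]")
    rank = np.linalg.matrix_rank(X.values - X.values.mean(axis=0))
    if m > rank:
        raise ValueError(f"m={m} exceeds the data rank; at most {rank} achievable")
    pca = PCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(X.values)
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]),
                         np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    scores = scores * flip[None, :]
    evr = pca.explained_variance_ratio_
    reducer = _PCAReducer(pca.mean_, comps[:m])
    emb = Embedding(
        method="pca",
        subject_ids=list(X.subject_ids),
        m=m,
        coordinates=scores[:, :m],
        reducer=reducer,
        diagnostics={
            "explained_variance_ratio": evr,
            "cumulative_variance_pct": 100.0 * np.cumsum(evr),
            "overfit": False,
        },
    )
    emb.diagnostics["train_mse"] = reconstruction_mse(emb, X)
    return emb


@dataclass
class AETrainConfig:
    epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 20
    hidden: int | None = None  # default max(96, ceil(sqrt(p*m)))
    test_fraction: float = 0.10


class _AutoencoderNet:
    """Symmetric tanh MLP autoencoder trained with Adam (pure numpy)."""

    def __init__(self, p: int, h: int, m: int, rng: np.random.Generator):
        def glorot(n_in, n_out):
            lim = math.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        self.params = {
            "W1": glorot(p, h), "b1": np.zeros(h),
            "W2": glorot(h, m), "b2": np.zeros(m),
            "W3": glorot(m, h), "b3": np.zeros(h),
            "W4": glorot(h, p), "b4": np.zeros(p),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    @property
    def n_features(self) -> int:
        return self.params["W1"].shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        P = self.params
        h1 = np.tanh(X @ P["W1"] + P["b1"])
        return h1 @ P["W2"] + P["b2"]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        P = self.params
        h2 = np.tanh(Z @ P["W3"] + P["b3"])
        return h2 @ P["W4"] + P["b4"]

    def mse(self, X: np.ndarray) -> float:
        return float(np.mean((self.decode(self.encode(X)) - X) ** 2))

    def _step(self, X: np.ndarray, lr: float):
        P = self.params
        h1 = np.tanh(X @ P["W1"] + P["b1"])
        z = h1 @ P["W2"] + P["b2"]
        h2 = np.tanh(z @ P["W3"] + P["b3"])
        out = h2 @ P["W4"] + P["b4"]
        diff = out - X
        loss = float(np.mean(diff**2))
        g = {}
        dout = (2.0 / diff.size) * diff
        g["W4"] = h2.T @ dout
        g["b4"] = dout.sum(axis=0)
        dh2 = (dout @ P["W4"].T) * (1.0 - h2**2)
        g["W3"] = z.T @ dh2
        g["b3"] = dh2.sum(axis=0)
        dz = dh2 @ P["W3"].T
        g["W2"] = h1.T @ dz
        g["b2"] = dz.sum(axis=0)
        dh1 = (dz @ P["W2"].T) * (1.0 - h1**2)
        g["W1"] = X.T @ dh1
        g["b1"] = dh1.sum(axis=0)

        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in P:
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g[k]
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g[k] ** 2
            mhat = self._adam_m[k] / (1 - b1**self._t)
            vhat = self._adam_v[k] / (1 - b2**self._t)
            P[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss


def fit_autoencoder(
    X: OmicsMatrix,
    m: int,
    train_cfg: AETrainConfig | None = None,
    seed: int = 0,
) -> Embedding:
    """Train the autoencoder and embed all subjects.

    A seeded 10% subject holdout provides the per-epoch test error; early
    stopping (patience on test MSE) restores the best weights. The returned
    coordinates cover every subject, including held-out ones.
    """
    cfg = train_cfg or AETrainConfig()
    n, p = X.values.shape
    if n < 20:
        raise ValueError("need at least 20 subjects to train the autoencoder")
    if m < 1:
        raise ValueError("embedding width must be >= 1")
    rng = np.random.default_rng(seed)
    h = cfg.hidden or max(96, math.ceil(math.sqrt(p * m)))

    perm = rng.permutation(n)
    n_test = max(1, int(round(cfg.test_fraction * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    Xtr, Xte = X.values[train_idx], X.values[test_idx]

    net = _AutoencoderNet(p, h, m, rng)
    history = {"train_mse": [], "test_mse": []}
    best = (math.inf, None, -1)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), cfg.batch_size):
            batch = Xtr[order[start:start + cfg.batch_size]]
            loss = net._step(batch, cfg.learning_rate)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    "autoencoder loss diverged; lower the learning rate"
                )
        tr, te = net.mse(Xtr), net.mse(Xte)
        history["train_mse"].append(tr)
        history["test_mse"].append(te)
        if te < best[0]:
            best = (te, {k: v.copy() for k, v in net.params.items()}, epoch)
        elif epoch - best[2] >= cfg.patience:
            break
    if best[1] is not None:
        net.params = best[1]
    train_mse, test_mse = net.mse(Xtr), net.mse(Xte)
    return Embedding(
        method="autoencoder",
        subject_ids=list(X.subject_ids),
        m=m,
        coordinates=net.encode(X.values),
        reducer=net,
        diagnostics={
            "train_mse": train_mse,
            "test_mse": test_mse,
            "overfit": overfit_flag(train_mse, test_mse),
            "history": history,
            "hidden": h,
            "test_subjects": [X.subject_ids[i] for i in test_idx],
        },
    )


def reconstruction_mse(emb: Embedding, X: OmicsMatrix) -> float:
    """Mean over all cells of the squared decode(encode(X)) - X difference."""
    reducer = emb.reducer
    if reducer is None:
        raise ValueError("embedding carries no reducer; cannot reconstruct")
    if getattr(reducer, "n_features", X.n_features) != X.n_features:
        raise ValueError(
            f"embedding was fitted on {reducer.n_features} features, "
            f"matrix has {X.n_features}"
        )
    recon = reducer.decode(reducer.encode(X.values))
    return float(np.mean((recon - X.values) ** 2))


def elbow_index(xs, ys) -> tuple:
    """Index of the point farthest (perpendicular) from the first-last chord.

    Both axes are normalised to [0, 1] first, so the choice is invariant to
    affine rescaling of either axis. Returns (index, distances).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3:
        raise ValueError("elbow undefined for fewer than 3 candidates")

    def norm(a):
        span = a[-1] - a[0]
        return (a - a[0]) / span if span != 0 else np.zeros_like(a)

    u, v = norm(xs), norm(ys)
    p0, p1 = np.array([u[0], v[0]]), np.array([u[-1], v[-1]])
    chord = p1 - p0
    L = np.hypot(*chord)
    if L == 0:
        dists = np.zeros(len(xs))
    else:
        dists = np.abs(chord[0] * (p0[1] - v) - (p0[0] - u) * chord[1]) / L
    interior = dists[1:-1]
    if interior.max(initial=0.0) < 1e-9:
        logger.warning("no elbow in diagnostic curve; using first interior point")
        return 1, dists
    return 1 + int(np.argmax(interior)), dists


def choose_num_dimensions(
    X: OmicsMatrix,
    candidates,
    method: str = "pca",
    seed: int = 0,
    train_cfg: AETrainConfig | None = None,
):
    """Pick the embedding width by the elbow of the diagnostic curve.

    PCA uses cumulative percent variance explained at each candidate width;
    the autoencoder retrains per candidate and uses held-out test MSE.
    Returns (chosen m, per-candidate diagnostic table).
    """
    candidates = sorted(int(c) for c in candidates)
    if len(candidates) < 3:
        raise ValueError("elbow undefined for fewer than 3 candidates")
    values = []
    if method == "pca":
        full = fit_pca(X, max(1, min(candidates[-1], min(X.values.shape))))
        cum = full.diagnostics["cumulative_variance_pct"]
        for c in candidates:
            values.append(cum[min(c, len(cum)) - 1])
    elif method == "autoencoder":
        for c in candidates:
            emb = fit_autoencoder(X, c, train_cfg=train_cfg, seed=seed)
            values.append(emb.diagnostics["test_mse"])
    else:
        raise ValueError(f"unknown method {method!r}")
    idx, dists = elbow_index(candidates, values)
    table = pd.DataFrame(
        {
            "m": candidates,
            "diagnostic": values,
            "chord_distance": dists,
            "chosen": [i == idx for i in range(len(candidates))],
        }
    )
    return candidates[idx], table


def shared_dimension(per_omic_elbows) -> int:
    """Resolve one width for all omics: the maximum of per-omic elbows."""
    return max(int(m) for m in per_omic_elbows)
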