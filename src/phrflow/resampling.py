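"""Minority-oversampling and majority-cleaning resamplers.

Implemented directly (k-NN based) with the classical definitions:

* SMOTE: each synthetic minority point lies uniformly on the segment
  between a minority point and one of its k minority nearest neighbors.
* ADASYN: as SMOTE, but the number of synthetic points seeded at each
  minority row is proportional to the fraction of majority points among
  its k nearest neighbors (harder rows get more synthesis).
* Tomek links: a pair (i, j) of opposite classes that are each other's
  nearest neighbor; the majority member of each link is removed.

Oversamplers only ever *add* minority rows; the link cleaner only ever
*removes* majority rows.  Both are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigurationError

__all__ = ["smote", "adasyn", "tomek_links"]


def _classes(y: np.ndarray) -> tuple[float, float]:
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2:
        raise ConfigurationError("resampling expects exactly two classes")
    minority = values[np.argmin(counts)]
    majority = values[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = values[1], values[0]  # deterministic tie-break
    return minority, majority


def _check_k(n_minority: int, k: int) -> None:
    if n_minority <= k:
        raise ConfigurationError(
            f"only {n_minority} minority rows for k={k} neighbors; "
            "reduce k_neighbors or collect more minority samples"
        )


def _synthesize(X_min: np.ndarray, per_seed_counts: np.ndarray, k: int,
                rng: np.random.Generator) -> np.ndarray:
    """Interpolate counts[i] points between row i and its minority k-NN."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # first neighbor is the point itself
    out = []
    for i, count in enumerate(per_seed_counts):
        for _ in range(int(count)):
            j = idx[i, rng.integers(1, k + 1)]
            lam = rng.random()
            out.append(X_min[i] + lam * (X_min[j] - X_min[i]))
    if not out:
        return np.empty((0, X_min.shape[1]))
    return np.vstack(out)


def smote(X: np.ndarray, y: np.ndarray, seed: int, k_neighbors: int = 5
          ) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity; no-op when already balanced."""
    minority, majority = _classes(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    n_new = n_maj - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    _check_k(n_min, k_neighbors)
    rng = np.random.default_rng(seed)
    base = np.full(n_min, n_new // n_min)
    extra = rng.choice(n_min, size=n_new % n_min, replace=False)
    base[extra] += 1
    X_syn = _synthesize(X[y == minority], base, k_neighbors, rng)
    return (np.vstack([X, X_syn]),
            np.concatenate([y, np.full(len(X_syn), minority)]))


def adasyn(X: np.ndarray, y: np.ndarray, seed: int, k_neighbors: int = 5
           ) -> tuple[np.ndarray, np.ndarray]:
    """Density-adaptive oversampling to parity; rows surrounded by majority
    neighbors receive proportionally more synthetic points."""
    minority, majority = _classes(y)
    n_min = int((y == minority).sum())
    n_maj = int((y == majority).sum())
    n_new = n_maj - n_min
    if n_new <= 0:
        return X.copy(), y.copy()
    _check_k(n_min, k_neighbors)
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]
    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn_all.kneighbors(X_min)
    maj_frac = (y[idx[:, 1:]] == majority).mean(axis=1)
    if maj_frac.sum() == 0:
        # perfectly separated data degenerates to uniform allocation
        maj_frac = np.ones(n_min)
    weights = maj_frac / maj_frac.sum()
    counts = np.floor(weights * n_new).astype(int)
    deficit = n_new - counts.sum()
    if deficit > 0:
        order = np.argsort(-weights)
        counts[order[:deficit]] += 1
    X_syn = _synthesize(X_min, counts, k_neighbors, rng)
    return (np.vstack([X, X_syn]),
            np.concatenate([y, np.full(len(X_syn), minority)]))


def tomek_links(X: np.ndarray, y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Remove the majority member of every opposite-class mutual-NN pair."""
    minority, majority = _classes(y)
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, idx = nn.kneighbors(X)
    nearest = idx[:, 1]
    drop = set()
    for i, j in enumerate(nearest):
        if y[i] != y[j] and nearest[j] == i:
            drop.add(i if y[i] == majority else j)
    keep = np.array([i for i in range(len(y)) if i not in drop], dtype=int)
    return X[keep], y[keep]
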