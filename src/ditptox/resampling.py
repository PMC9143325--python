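"""SMOTE: synthetic minority oversampling by neighbor interpolation.

Each synthetic minority sample is x + u * (x_nn - x) with u ~ Uniform(0, 1)
and x_nn one of x's k nearest minority-class neighbors in Euclidean
distance — a convex combination of exactly two original minority points.
Majority rows are never altered or duplicated, original rows stay first in
their original order, and a fixed seed gives identical output.

The neighbor search is exact (brute force); the intended datasets are a
few hundred rows. Resampling is meant to run inside each training fold
only, never on validation folds or external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SmoteConfig", "SmoteError", "smote_oversample"]


class SmoteError(ValueError):
    pass


@dataclass(frozen=True)
class SmoteConfig:
    """k_neighbors: neighbor pool size; target_ratio: minority/majority
    after resampling (1.0 balances fully); seed: RNG seed."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise SmoteError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise SmoteError("target_ratio must lie in (0, 1]")


def smote_oversample(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig = SmoteConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class of a binary problem up to the target
    minority/majority ratio. Returns (X', y') with the original rows first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise SmoteError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise SmoteError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise SmoteError("SMOTE needs exactly two classes")

    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_target = int(np.ceil(cfg.target_ratio * n_maj))
    n_new = max(0, n_target - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise SmoteError("minority class of size 1 cannot form a neighbor pair")

    k = cfg.k_neighbors
    if k >= n_min:
        warnings.warn(
            f"k_neighbors={k} >= minority size {n_min}; reduced to {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    Xmin = X[y == minority]
    dist = cdist(Xmin, Xmin)
    np.fill_diagonal(dist, np.inf)
    # k nearest minority neighbors per minority point (ties by index order)
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    anchors = Xmin[base]
    partners = Xmin[nn[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out
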