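"""Euclidean-distance applicability domain (AD).

The AD answers "is this molecule close enough to the training chemistry
for the model's prediction to be trusted?". The default statistic is the
nearest-neighbor distance: for each training row its leave-one-out
nearest-neighbor Euclidean distance is computed, and the threshold is the
95th-percentile (configurable) of those distances. A query is inside the
domain iff its distance to the nearest training row is at most the
threshold; training rows self-match at distance 0, so training coverage
is 100% by construction. A centroid-distance alternative is available via
``method='centroid'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = ["ADModel", "ADError", "fit_ad", "assess_ad", "ad_coverage"]


class ADError(ValueError):
    pass


@dataclass
class ADModel:
    """Reference (normalized training) feature matrix plus the distance
    threshold at the fitted percentile."""

    reference: np.ndarray
    threshold: float
    percentile: float
    method: str = "nn"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.size == 0:
            raise ADError("reference matrix must be non-empty")
        if self.threshold < 0:
            raise ADError("threshold must be non-negative")


def fit_ad(
    train_features: np.ndarray, percentile: float = 0.95, method: str = "nn"
) -> ADModel:
    """Fit the domain on training features (rows = training molecules).

    ``nn``: threshold = percentile-quantile of leave-one-out nearest-
    neighbor distances. ``centroid``: threshold = percentile-quantile of
    distances to the training centroid.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ADError("fitting the AD needs at least 3 training rows")
    if not np.isfinite(X).all():
        raise ADError("training features must be finite")
    if not 0 < percentile <= 1:
        raise ADError("percentile must lie in (0, 1]")
    if method == "nn":
        d = squareform(pdist(X))
        np.fill_diagonal(d, np.inf)
        loo_nn = d.min(axis=1)
        threshold = float(np.quantile(loo_nn, percentile))
    elif method == "centroid":
        centroid = X.mean(axis=0, keepdims=True)
        dists = cdist(X, centroid).ravel()
        threshold = float(np.quantile(dists, percentile))
    else:
        raise ADError(f"unknown AD method {method!r}")
    return ADModel(X, threshold, percentile, method)


def _distance(model: ADModel, X: np.ndarray) -> np.ndarray:
    if X.shape[1] != model.reference.shape[1]:
        raise ADError(
            f"query dimensionality {X.shape[1]} != reference "
            f"{model.reference.shape[1]}"
        )
    if model.method == "nn":
        return cdist(X, model.reference).min(axis=1)
    centroid = model.reference.mean(axis=0, keepdims=True)
    return cdist(X, centroid).ravel()


def assess_ad(model: ADModel, x: np.ndarray) -> tuple[bool, float]:
    """Inside/outside flag and distance for one feature vector.

    Distance is to the nearest reference row (self-matches at 0 allowed);
    a point exactly at the threshold counts as inside.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = float(_distance(model, x)[0])
    return d <= model.threshold, d


def ad_coverage(
    model: ADModel, X: np.ndarray, labels: np.ndarray | None = None
) -> dict:
    """Coverage report for a set of molecules.

    ``coverage_pct`` is 100 * n_inside / n rounded to 1 d.p.; per-class
    inside/outside counts are included when labels are supplied.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ADError("coverage needs a non-empty feature matrix")
    d = _distance(model, X)
    inside = d <= model.threshold
    n = len(inside)
    report: dict = {
        "n": n,
        "n_inside": int(inside.sum()),
        "n_outside": int(n - inside.sum()),
        "coverage_pct": round(100.0 * inside.sum() / n, 1),
        "threshold": model.threshold,
        "percentile": model.percentile,
        "distances": d,
        "inside": inside,
    }
    if labels is not None:
        y = np.asarray(labels)
        report["per_class"] = {
            "inside_pos": int((inside & (y == 1)).sum()),
            "inside_neg": int((inside & (y == 0)).sum()),
            "outside_pos": int((~inside & (y == 1)).sum()),
            "outside_neg": int((~inside & (y == 0)).sum()),
        }
    return report
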