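"""Reference open-set decision rules: OSNN-CV, OSNN-NNDR and NCM.

All three operate on raw Euclidean distances in feature space.

* OSNN-CV (class verification): accept with the shared label of the two
  nearest training samples if they agree, otherwise reject as unknown.
* OSNN-NNDR (nearest-neighbor distance ratio): with t the nearest training
  sample and u the nearest sample of a different class, accept with the
  class of t when R = d(z,t)/d(z,u) falls below a threshold T.
* NCM (nearest class mean): accept with the label of the nearest class
  centroid when that distance falls below a threshold T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import UNKNOWN_LABEL, FeatureTable

__all__ = [
    "NCMModel",
    "osnn_cv_predict",
    "osnn_nndr_predict",
    "ncm_fit",
    "ncm_predict",
    "ncm_tune_threshold",
]


def _as_queries(z) -> tuple[np.ndarray, bool]:
    Z = np.asarray(z, dtype=float)
    single = Z.ndim == 1
    return np.atleast_2d(Z), single


def osnn_cv_predict(train: FeatureTable, z):
    """Class-verification rule: the two nearest training samples must agree.

    Accepts a single feature row or a 2-D stack of rows; distance ties are
    broken by the lowest training-sample index.
    """
    if train.n < 2:
        raise ValueError("OSNN-CV requires at least 2 training samples")
    Z, single = _as_queries(z)
    D = cdist(Z, train.X)
    # stable argsort -> lowest index wins ties
    nn2 = np.argsort(D, axis=1, kind="stable")[:, :2]
    out = []
    for a, b in nn2:
        la, lb = train.labels[a], train.labels[b]
        out.append(la if la == lb else UNKNOWN_LABEL)
    return out[0] if single else out


def osnn_nndr_predict(train: FeatureTable, z, T: float):
    """Nearest-neighbor distance-ratio rule.

    R = d(z, t) / d(z, u) with t the overall nearest training sample and u
    the nearest sample in any other class; accept class(t) iff R < T.
    A query coinciding with a training point has R = 0 and is accepted.
    """
    if T <= 0:
        raise ValueError("threshold T must be positive")
    labels = np.asarray(train.labels)
    if len(set(train.labels)) < 2:
        raise ValueError("OSNN-NNDR needs >= 2 training classes for the ratio")
    Z, single = _as_queries(z)
    D = cdist(Z, train.X)
    out = []
    for row in D:
        t = int(np.argmin(row))
        dt = row[t]
        other = labels != labels[t]
        du = row[other].min()
        if dt == 0.0:
            out.append(train.labels[t])
        elif du == 0.0 or dt / du < T:
            # du == 0 with dt > 0 cannot occur for the argmin t; guard anyway
            out.append(train.labels[t] if du > 0.0 else UNKNOWN_LABEL)
        else:
            out.append(UNKNOWN_LABEL)
    return out[0] if single else out


@dataclass
class NCMModel:
    """Per-class centroids plus a rejection threshold T on raw distance."""

    class_labels: list[str]
    centroids: np.ndarray
    threshold: float


def ncm_fit(train: FeatureTable, T: float) -> NCMModel:
    """Compute per-class mean feature rows; classes ordered by label sort."""
    if T <= 0:
        raise ValueError("threshold T must be positive")
    labels = sorted(set(train.labels))
    if not labels:
        raise ValueError("empty training set")
    arr = np.asarray(train.labels)
    cents = []
    for lab in labels:
        mask = arr == lab
        if not mask.any():
            raise ValueError(f"class {lab!r} has no samples")
        cents.append(train.X[mask].mean(axis=0))
    return NCMModel(class_labels=labels, centroids=np.vstack(cents), threshold=T)


def ncm_predict(model: NCMModel, z):
    """Label of the nearest centroid if closer than T, else UNKNOWN.

    Centroid distance ties resolve to the first label in sort order
    (argmin on the label-sorted centroid array).
    """
    Z, single = _as_queries(z)
    D = cdist(Z, model.centroids)
    idx = np.argmin(D, axis=1)
    dmin = D[np.arange(len(Z)), idx]
    out = [
        model.class_labels[i] if d < model.threshold else UNKNOWN_LABEL
        for i, d in zip(idx, dmin)
    ]
    return out[0] if single else out


def ncm_tune_threshold(
    train: FeatureTable, folds: int = 3, seed: int = 0, n_grid: int = 20
) -> float:
    """Pick T by stratified CV on known-class data only.

    Candidate thresholds are quantiles of the training distance-to-own-
    centroid distribution (upper tail stretched 1.5x); the selected T
    maximizes mean held-out acceptance, ties resolved to the smallest T —
    the tightest threshold that still covers the known classes.  No
    unknown-class information is used.
    """
    arr = np.asarray(train.labels)
    cents = ncm_fit(train, T=1.0)
    lab_to_row = {l: i for i, l in enumerate(cents.class_labels)}
    own = np.array(
        [
            np.linalg.norm(train.X[i] - cents.centroids[lab_to_row[arr[i]]])
            for i in range(train.n)
        ]
    )
    qs = np.linspace(0.5, 1.0, n_grid)
    grid = np.unique(np.concatenate([np.quantile(own, qs), [own.max() * 1.5]]))
    grid = grid[grid > 0]

    rng = np.random.default_rng(seed)
    fold_of = np.empty(train.n, dtype=int)
    for lab in set(train.labels):
        idx = np.flatnonzero(arr == lab)
        idx = idx[rng.permutation(len(idx))]
        fold_of[idx] = np.arange(len(idx)) % folds
    rates = np.zeros(len(grid))
    for f in range(folds):
        tr = train.subset(fold_of != f)
        ho = train.subset(fold_of == f)
        m = ncm_fit(tr, T=1.0)
        d = cdist(ho.X, m.centroids).min(axis=1)
        for gi, T in enumerate(grid):
            rates[gi] += np.mean(d < T)
    rates /= folds
    best = np.flatnonzero(rates == rates.max())
    return float(grid[best[0]])  # grid ascending -> smallest T among ties
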