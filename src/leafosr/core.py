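"""Shared domain types and kernel functions.

The universal data currency is a :class:`FeatureTable`: ``n`` samples with
string labels and a dense ``n x d`` real feature matrix, standing in for
image embeddings (e.g. the 1x1000 FC-layer output of a CNN backbone).
Kernels follow the LibSVM parameterization: the RBF kernel is
``k(x, y) = exp(-gamma * ||x - y||^2)`` with a single width parameter
``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "UNKNOWN_LABEL",
    "FeatureTable",
    "KernelSpec",
    "SampleWeights",
    "kernel_eval",
    "gram_matrix",
    "cross_gram",
]

#: Reserved prediction label for samples rejected as not belonging to any
#: known class.  Class labels in data files are opaque strings; this one
#: literal is reserved for predictions.
UNKNOWN_LABEL = "UNKNOWN"


@dataclass
class FeatureTable:
    """n samples x d features with per-sample ids and class labels.

    Parameters
    ----------
    ids
        Unique sample identifiers, length n.
    labels
        Class labels (opaque strings), length n.
    X
        Real feature matrix of shape (n, d); all entries must be finite.
    """

    ids: list[str]
    labels: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        n = self.X.shape[0]
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError(
                f"inconsistent lengths: {len(self.ids)} ids, "
                f"{len(self.labels)} labels, {n} feature rows"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        self.ids = [str(i) for i in self.ids]
        self.labels = [str(l) for l in self.labels]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureTable":
        """New table holding the rows selected by integer/boolean index."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            X=self.X[idx],
        )

    def class_labels(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l)
        return list(seen)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel specification: ``rbf`` (with width gamma) or ``linear``."""

    kind: str = "rbf"
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and not self.gamma > 0:
            raise ValueError(f"rbf gamma must be positive, got {self.gamma}")


@dataclass
class SampleWeights:
    """Per-sample slack-penalty weights in (0, 1], normalized so max(w) = 1.

    Uniform weights recover standard SVDD; weights shrinking toward 0 for
    outlying samples give the weighted variant its robustness.
    """

    w: np.ndarray = field(default_factory=lambda: np.ones(0))

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.w.size and not np.all(self.w > 0):
            raise ValueError("all weights must be strictly positive")
        if self.w.size and abs(self.w.max() - 1.0) > 1e-12:
            raise ValueError("weights must be normalized so max(w) == 1")


def _check_dims(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"dimension mismatch: x has {x.shape[-1]} features, "
            f"y has {y.shape[-1]}"
        )


def kernel_eval(x, y, spec: KernelSpec) -> float:
    """Evaluate k(x, y) for two feature rows."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    _check_dims(x, y)
    if spec.kind == "linear":
        return float(x @ y)
    diff = x - y
    return float(np.exp(-spec.gamma * (diff @ diff)))


def gram_matrix(X, spec: KernelSpec) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = k(X[i], X[j]).

    Symmetric and positive semidefinite; for the RBF kernel every entry is
    in (0, 1] and the diagonal is exactly 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("gram_matrix requires at least one sample")
    if not np.all(np.isfinite(X)):
        raise ValueError("gram_matrix input contains non-finite values")
    if spec.kind == "linear":
        K = X @ X.T
    else:
        d2 = cdist(X, X, metric="sqeuclidean")
        K = np.exp(-spec.gamma * d2)
        np.fill_diagonal(K, 1.0)
    # enforce exact symmetry against floating-point asymmetry in BLAS
    return (K + K.T) / 2.0


def cross_gram(X, Z, spec: KernelSpec) -> np.ndarray:
    """Rectangular kernel matrix K[i, j] = k(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _check_dims(X, Z)
    if spec.kind == "linear":
        return X @ Z.T
    return np.exp(-spec.gamma * cdist(X, Z, metric="sqeuclidean"))
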