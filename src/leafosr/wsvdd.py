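"""Weighted support vector data description (wSVDD).

SVDD finds the smallest hypersphere (center ``c``, radius ``R``) in kernel
space that encloses the training data, with slack variables ``xi_i``
penalized by a cost ``C``.  The weighted variant scales each sample's slack
penalty by a weight ``w_i`` in (0, 1], so concentrated samples constrain
the sphere more strongly than outliers.  The dual problem solved here is

    max  sum_i a_i K_ii - sum_ij a_i a_j K_ij
    s.t. sum_i a_i = 1,   0 <= a_i <= C * w_i

The solver is a deterministic SMO-style maximal-violating-pair coordinate
ascent; no randomness is involved anywhere in training.

A model predicts membership by comparing the squared kernel-space distance
to the center,

    d^2(z) = k(z, z) - 2 sum_i a_i k(x_i, z) + sum_ij a_i a_j k(x_i, x_j),

against the squared radius ``R^2`` estimated from the unbounded support
vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import (
    FeatureTable,
    KernelSpec,
    SampleWeights,
    cross_gram,
    gram_matrix,
    kernel_eval,
)

__all__ = [
    "WSVDDModel",
    "default_weights",
    "solve_dual",
    "fit",
    "fit_oneclass",
    "squared_center_distance",
    "predict_membership",
    "model_to_json",
    "model_from_json",
]

DEFAULT_TOL = 1e-6


@dataclass
class WSVDDModel:
    """Trained hypersphere: support expansion of the center plus R^2.

    ``sv_rows``/``alphas`` hold only the support vectors (alpha above the
    fit tolerance); ``center_term`` caches the constant
    ``sum_ij a_i a_j k(x_i, x_j)`` of the distance expansion.
    """

    sv_rows: np.ndarray
    alphas: np.ndarray
    kernel: KernelSpec
    C: float
    r2: float
    center_term: float
    variant: str = "wsvdd"
    slacks: np.ndarray | None = None
    tol: float = DEFAULT_TOL

    @property
    def n_support(self) -> int:
        return len(self.alphas)


def default_weights(X, spec: KernelSpec, scheme: str = "centroid") -> SampleWeights:
    """Sample weights from kernel-space distance to the empirical centroid.

    ``uniform`` gives all-ones (standard SVDD).  ``centroid`` computes the
    squared kernel distance of each sample to the mean of the mapped data,

        d_i^2 = K_ii - (2/n) sum_j K_ij + (1/n^2) sum_jl K_jl,

    and sets ``w_i = exp(-d_i^2 / (2 * median_j d_j^2))`` rescaled so the
    largest weight is 1: concentrated samples get weight near 1, outliers
    decay smoothly toward 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot compute weights for an empty sample set")
    if scheme == "uniform":
        return SampleWeights(np.ones(n))
    if scheme != "centroid":
        raise ValueError(f"unknown weight scheme {scheme!r}")
    K = gram_matrix(X, spec)
    d2 = np.diag(K) - 2.0 * K.mean(axis=1) + K.mean()
    d2 = np.maximum(d2, 0.0)
    scale = float(np.median(d2))
    if scale <= 0.0:
        scale = float(np.mean(d2))
    if scale <= 0.0:  # all points identical
        return SampleWeights(np.ones(n))
    w = np.exp(-d2 / (2.0 * scale))
    return SampleWeights(w / w.max())


def _feasible_start(upper: np.ndarray) -> np.ndarray:
    """Uniform 1/n clipped to the box, deficit spread over slack capacity."""
    n = len(upper)
    alpha = np.minimum(np.full(n, 1.0 / n), upper)
    deficit = 1.0 - alpha.sum()
    # distribute the clipped mass proportionally to remaining capacity
    for _ in range(n):
        if deficit <= 1e-15:
            break
        room = upper - alpha
        open_idx = room > 1e-15
        add = np.zeros(n)
        add[open_idx] = room[open_idx] / room[open_idx].sum() * deficit
        alpha = np.minimum(alpha + add, upper)
        deficit = 1.0 - alpha.sum()
    return alpha


def solve_dual(
    K: np.ndarray,
    w: SampleWeights,
    C: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = 1_000_000,
) -> np.ndarray:
    """Maximize the wSVDD dual by deterministic maximal-violating-pair SMO.

    Parameters
    ----------
    K
        Symmetric PSD gram matrix (n x n).
    w
        Sample weights; the box constraint is ``0 <= a_i <= C * w_i``.
    C
        Penalty cost; ``sum_i C*w_i >= 1`` is required for feasibility.
    tol
        Convergence threshold on the maximal KKT violation.

    Returns
    -------
    alphas : length-n vector summing to 1 within the box constraints.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError(f"gram matrix must be square, got {K.shape}")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("gram matrix must be symmetric")
    if n <= 1000:
        min_eig = float(np.linalg.eigvalsh(K)[0])
        if min_eig < -1e-8 * max(1.0, float(np.abs(K).max())):
            raise ValueError(
                f"gram matrix is not positive semidefinite "
                f"(smallest eigenvalue {min_eig:.3e})"
            )
    upper = C * np.asarray(w.w, dtype=float)
    if len(upper) != n:
        raise ValueError(f"{len(upper)} weights for {n} samples")
    if upper.sum() < 1.0 - 1e-12:
        raise ValueError(
            f"infeasible problem: sum(C*w) = {upper.sum():.6g} < 1; "
            f"increase C"
        )
    if n == 1:
        return np.ones(1)

    alpha = _feasible_start(upper)
    Ka = K @ alpha
    diag = np.diag(K).copy()
    eps = 1e-12
    for _ in range(max_iter):
        g = diag - 2.0 * Ka  # gradient of the dual objective
        can_up = alpha < upper - eps
        can_dn = alpha > eps
        # maximal violating pair: raise where gradient is largest,
        # lower where it is smallest
        gi = np.where(can_up, g, -np.inf)
        gj = np.where(can_dn, g, np.inf)
        i = int(np.argmax(gi))
        j = int(np.argmin(gj))
        viol = gi[i] - gj[j]
        if viol < tol:
            break
        denom = 2.0 * (diag[i] + diag[j] - 2.0 * K[i, j])
        if denom > eps:
            t = viol / denom
        else:
            t = np.inf  # flat direction: take the largest feasible step
        t = min(t, upper[i] - alpha[i], alpha[j])
        alpha[i] += t
        alpha[j] -= t
        Ka += t * (K[:, i] - K[:, j])
    else:
        raise RuntimeError(
            f"SMO did not converge in {max_iter} iterations "
            f"(violation {viol:.3e}, tol {tol:.3e})"
        )
    return alpha


def fit(
    table: FeatureTable,
    w: SampleWeights,
    C: float,
    kernel: KernelSpec,
    tol: float = DEFAULT_TOL,
    variant: str = "wsvdd",
) -> WSVDDModel:
    """Train a weighted SVDD model on all rows of ``table``.

    R^2 is the mean squared center distance over unbounded support vectors
    (``tol < a_i < C*w_i - tol``), which lie exactly on the sphere in exact
    arithmetic; averaging damps floating-point spread.  If no support
    vector is unbounded, R^2 falls back to the largest squared center
    distance among samples strictly below their upper bound.
    """
    X = table.X
    K = gram_matrix(X, kernel)
    alpha = solve_dual(K, w, C, tol=tol)
    upper = C * w.w
    # zero the sub-tolerance stragglers and renormalize so the stored
    # support expansion is exactly the one used for r2 and distances
    alpha = np.where(alpha > tol, alpha, 0.0)
    alpha /= alpha.sum()
    center_term = float(alpha @ K @ alpha)
    d2 = np.maximum(np.diag(K) - 2.0 * (K @ alpha) + center_term, 0.0)

    unbounded = (alpha > tol) & (alpha < upper - tol)
    if np.any(unbounded):
        r2 = float(d2[unbounded].mean())
    else:
        below_cap = alpha < upper - tol
        r2 = float(d2[below_cap].max()) if np.any(below_cap) else float(d2.max())
    r2 = max(r2, 0.0)
    slacks = np.maximum(d2 - r2, 0.0)

    sv = alpha > tol
    return WSVDDModel(
        sv_rows=X[sv].copy(),
        alphas=alpha[sv].copy(),
        kernel=kernel,
        C=float(C),
        r2=r2,
        center_term=center_term,
        variant=variant,
        slacks=slacks,
        tol=tol,
    )


def fit_oneclass(
    table: FeatureTable,
    C: float,
    kernel: KernelSpec,
    variant: str = "wsvdd",
    tol: float = DEFAULT_TOL,
) -> WSVDDModel:
    """Train a one-class model in one of three variants.

    ``wsvdd`` uses centroid-distance weights; ``svdd`` uses uniform
    weights; ``ocsvm`` also uses uniform weights, relying on the standard
    equivalence that for unit-diagonal kernels (RBF) the one-class SVM
    hyperplane and the SVDD sphere induce identical accept/reject
    decisions.
    """
    if variant not in ("wsvdd", "svdd", "ocsvm"):
        raise ValueError(f"unknown variant {variant!r}")
    scheme = "centroid" if variant == "wsvdd" else "uniform"
    w = default_weights(table.X, kernel, scheme=scheme)
    return fit(table, w, C, kernel, tol=tol, variant=variant)


def squared_center_distance(model: WSVDDModel, z) -> float:
    """Squared kernel-space distance from a feature row to the center."""
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != model.sv_rows.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.sv_rows.shape[1]} "
            f"features, query has {z.shape[0]}"
        )
    kzz = kernel_eval(z, z, model.kernel)
    kxz = cross_gram(model.sv_rows, z[None, :], model.kernel).ravel()
    d2 = kzz - 2.0 * float(model.alphas @ kxz) + model.center_term
    return max(d2, 0.0)


def predict_membership(model: WSVDDModel, Z: FeatureTable):
    """Accept/reject each row of ``Z`` against the trained sphere.

    Returns
    -------
    accepted : boolean array, True where the sample falls inside the sphere
    scores : ``r2 - d^2`` (positive inside, negative outside)
    """
    X = Z.X if isinstance(Z, FeatureTable) else np.atleast_2d(np.asarray(Z, float))
    if X.shape[1] != model.sv_rows.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.sv_rows.shape[1]} "
            f"features, input has {X.shape[1]}"
        )
    if model.kernel.kind == "rbf":
        kzz = np.ones(X.shape[0])
    else:
        kzz = np.einsum("ij,ij->i", X, X)
    kxz = cross_gram(model.sv_rows, X, model.kernel)
    d2 = np.maximum(kzz - 2.0 * (model.alphas @ kxz) + model.center_term, 0.0)
    # boundary SVs agree on d^2 only to within the solver tolerance, so the
    # acceptance margin includes model.tol on top of the relative slack
    accepted = d2 <= model.r2 * (1.0 + 1e-9) + 1e-12 + model.tol
    scores = model.r2 - d2
    return accepted, scores


def model_to_json(model: WSVDDModel) -> str:
    """Serialize a model to JSON; floats round-trip exactly."""
    return json.dumps(
        {
            "kernel": {"kind": model.kernel.kind, "gamma": model.kernel.gamma},
            "C": model.C,
            "variant": model.variant,
            "tol": model.tol,
            "r2": model.r2,
            "center_term": model.center_term,
            "alphas": model.alphas.tolist(),
            "sv_rows": model.sv_rows.tolist(),
            "slacks": None if model.slacks is None else model.slacks.tolist(),
        },
        indent=1,
    )


def model_from_json(doc: str) -> WSVDDModel:
    d = json.loads(doc)
    return WSVDDModel(
        sv_rows=np.asarray(d["sv_rows"], dtype=float),
        alphas=np.asarray(d["alphas"], dtype=float),
        kernel=KernelSpec(kind=d["kernel"]["kind"], gamma=d["kernel"]["gamma"]),
        C=d["C"],
        r2=d["r2"],
        center_term=d["center_term"],
        variant=d.get("variant", "wsvdd"),
        slacks=None if d.get("slacks") is None else np.asarray(d["slacks"], float),
        tol=d.get("tol", DEFAULT_TOL),
    )
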