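"""Two-stage open-set recognition pipeline and hyperparameter search.

Stage 1 pools all known-class training features (labels ignored) into a
single one-class model — by default a weighted SVDD hypersphere — that
accepts or rejects each test sample.  Stage 2 assigns a species label to
every accepted sample with a pluggable multi-class backend (any object
with ``fit(X, labels)`` / ``predict(X)``); rejected samples receive the
reserved UNKNOWN label.  The default backend is a nearest-class-mean
classifier, standing in for the trained CNN / LibSVM stage of a full
image pipeline.

Hyperparameters (gamma, C) are chosen by grid search using only
known-class training data.  Two selection criteria are provided.  The
default, ``loco_f1``, holds out one known class at a time as a surrogate
unknown, fits stage 1 on the rest, and scores the open-set detection F1
(held-out knowns accepted, the surrogate class rejected) — simulating
openness with the classes at hand, as is standard practice in open-set
validation.  The alternative ``acceptance`` criterion maximizes the
held-out acceptance rate under stratified k-fold CV; it measures coverage
only, so it is monotone in sphere looseness and degenerates to the
loosest grid point — kept for diagnostics.  Ties prefer larger gamma (the
tightest sphere among equals) and then smaller C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import UNKNOWN_LABEL, FeatureTable, KernelSpec
from .wsvdd import WSVDDModel, fit_oneclass, predict_membership

__all__ = [
    "NearestClassMeanBackend",
    "OneClassParams",
    "OpenSetModel",
    "OpenSetPrediction",
    "fit_openset",
    "predict_openset",
    "grid_search",
]


class NearestClassMeanBackend:
    """Default multi-class backend: label of the nearest class centroid.

    Distance ties resolve to the first label in sort order.  Any object
    honoring the same fit/predict contract may replace it.
    """

    def __init__(self) -> None:
        self.class_labels: list[str] = []
        self.centroids: np.ndarray | None = None

    def fit(self, X, labels) -> "NearestClassMeanBackend":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        self.class_labels = sorted(set(labels.tolist()))
        self.centroids = np.vstack(
            [X[labels == lab].mean(axis=0) for lab in self.class_labels]
        )
        return self

    def predict(self, X) -> list[str]:
        if self.centroids is None:
            raise RuntimeError("backend is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        idx = np.argmin(cdist(X, self.centroids), axis=1)
        return [self.class_labels[i] for i in idx]


@dataclass(frozen=True)
class OneClassParams:
    """Stage-1 configuration; defaults are the tuned operating point
    gamma = 0.5, cost = 7.5 with the weighted variant."""

    kernel: KernelSpec = KernelSpec("rbf", 0.5)
    C: float = 7.5
    variant: str = "wsvdd"
    tol: float = 1e-6


@dataclass
class OpenSetModel:
    oneclass: WSVDDModel | list[WSVDDModel]
    backend: object
    known_labels: list[str]
    mode: str = "pooled"


@dataclass
class OpenSetPrediction:
    """Per-sample final label plus the stage-1 score and decision."""

    final_labels: list[str]
    stage1_scores: np.ndarray
    stage1_accepted: np.ndarray


def fit_openset(
    train: FeatureTable,
    params: OneClassParams | None = None,
    backend=None,
    mode: str = "pooled",
) -> OpenSetModel:
    """Fit stage 1 on the pooled training rows and stage 2 on the labels.

    ``mode='per-class'`` instead fits one sphere per known class and
    accepts a sample if any class sphere does (exploratory alternative to
    the single pooled sphere).
    """
    if train.n == 0:
        raise ValueError("empty training set")
    if mode not in ("pooled", "per-class"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or OneClassParams()
    backend = backend if backend is not None else NearestClassMeanBackend()
    known = sorted(set(train.labels))
    if mode == "pooled":
        oneclass = fit_oneclass(
            train, C=params.C, kernel=params.kernel, variant=params.variant,
            tol=params.tol,
        )
    else:
        arr = np.asarray(train.labels)
        oneclass = [
            fit_oneclass(
                train.subset(arr == lab),
                C=params.C, kernel=params.kernel, variant=params.variant,
                tol=params.tol,
            )
            for lab in known
        ]
    backend.fit(train.X, train.labels)
    return OpenSetModel(oneclass=oneclass, backend=backend, known_labels=known, mode=mode)


def predict_openset(model: OpenSetModel, test: FeatureTable) -> OpenSetPrediction:
    """Stage-1 accept/reject, then backend labels for accepted samples."""
    if model.mode == "pooled":
        accepted, scores = predict_membership(model.oneclass, test)
    else:
        per = [predict_membership(m, test) for m in model.oneclass]
        acc = np.vstack([a for a, _ in per])
        sc = np.vstack([s for _, s in per])
        accepted = acc.any(axis=0)
        scores = sc.max(axis=0)
    final = [UNKNOWN_LABEL] * test.n
    if accepted.any():
        backend_labels = model.backend.predict(test.X[accepted])
        for pos, lab in zip(np.flatnonzero(accepted), backend_labels):
            final[pos] = lab
    return OpenSetPrediction(
        final_labels=final, stage1_scores=scores, stage1_accepted=accepted
    )


def _stratified_folds(labels, folds: int, seed: int) -> np.ndarray:
    """Seeded per-class round-robin fold assignment."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=int)
    for lab in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        fold_of[idx] = np.arange(len(idx)) % folds
    return fold_of


def _detection_f1(acc_known: np.ndarray, acc_unknown: np.ndarray) -> float:
    kr = int(acc_known.sum())
    ke = int(len(acc_known) - kr)
    uke = int(acc_unknown.sum())
    p = kr / (kr + uke) if kr + uke else 0.0
    r = kr / (kr + ke) if kr + ke else 0.0
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def grid_search(
    train: FeatureTable,
    gammas,
    costs,
    folds: int = 3,
    seed: int = 0,
    variant: str = "wsvdd",
    tol: float = 1e-6,
    criterion: str = "loco_f1",
):
    """Select (gamma, C) by cross-validation on known-class data only.

    ``criterion='loco_f1'`` (default): for each known class c, fit the
    one-class stage on a stratified 80% share of the other classes and
    score the detection F1 with the held-out 20% as knowns and all of
    class c as surrogate unknowns; the grid point maximizing the mean F1
    over classes wins.  Requires >= 2 training classes.

    ``criterion='acceptance'``: stratified k-fold, score the held-out
    acceptance rate (coverage only; selects the loosest grid point on
    unimodal data — diagnostic use).

    Ties prefer larger gamma, then smaller C.  Returns the selected pair
    and the full table of per-fold scores.  Deterministic given ``seed``.
    """
    gammas = list(gammas)
    costs = list(costs)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if not gammas or not costs:
        raise ValueError("empty hyperparameter grid")
    if criterion not in ("loco_f1", "acceptance"):
        raise ValueError(f"unknown criterion {criterion!r}")
    labels = np.asarray(train.labels)
    classes = sorted(set(train.labels))
    if criterion == "loco_f1" and len(classes) < 2:
        criterion = "acceptance"  # no surrogate unknown available

    if criterion == "acceptance":
        splits = []  # (stage1-train, held-out knowns, surrogate unknowns)
        fold_of = _stratified_folds(train.labels, folds, seed)
        for f in range(folds):
            lost = set(classes) - set(labels[fold_of != f])
            if lost:
                warnings.warn(
                    f"fold {f} training part lost classes {sorted(lost)}",
                    stacklevel=2,
                )
            splits.append((train.subset(fold_of != f), train.subset(fold_of == f), None))
    else:
        rng = np.random.default_rng(seed)
        splits = []
        for c in classes:
            rest = train.subset(labels != c)
            rest_labels = np.asarray(rest.labels)
            keep = np.zeros(rest.n, dtype=bool)
            for lab in sorted(set(rest.labels)):
                idx = np.flatnonzero(rest_labels == lab)
                idx = idx[rng.permutation(len(idx))]
                keep[idx[: int(np.floor(0.8 * len(idx)))]] = True
            splits.append(
                (rest.subset(keep), rest.subset(~keep), train.subset(labels == c))
            )

    table_rows = []
    best = None  # (score, gamma, -C) maximized lexicographically
    for gamma in gammas:
        for C in costs:
            kernel = KernelSpec("rbf", gamma)
            scores = []
            for tr, ho, surrogate in splits:
                try:
                    m = fit_oneclass(tr, C=C, kernel=kernel, variant=variant, tol=tol)
                except ValueError:
                    scores.append(0.0)  # infeasible C at this split size
                    continue
                acc_k, _ = predict_membership(m, ho)
                if surrogate is None:
                    scores.append(float(np.mean(acc_k)))
                else:
                    acc_u, _ = predict_membership(m, surrogate)
                    scores.append(_detection_f1(acc_k, acc_u))
            mean_score = float(np.mean(scores))
            table_rows.append(
                {"gamma": gamma, "C": C, "fold_scores": scores, "mean": mean_score}
            )
            key = (mean_score, gamma, -C)
            if best is None or key > best[0]:
                best = (key, gamma, C)
    _, gamma, C = best
    return gamma, C, table_rows
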