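"""Open-set evaluation: detection F1, overall accuracy and Cohen's kappa.

The open-set F1 measures *detection* — whether known-class test samples
are accepted as known (any known label counts) and unknown-class samples
rejected:

    precision = kr / (kr + uke)       recall = kr / (kr + ke)
    F1 = 2 * precision * recall / (precision + recall)

with kr = known accepted, ke = known rejected as UNKNOWN, uke = unknown
wrongly accepted.  Species-level correctness is scored separately by the
overall accuracy P0 and Cohen's kappa over a (K+1)-class confusion matrix
(K known species plus one collapsed UNKNOWN class):

    Pe = sum_i row_i * col_i / n^2       kappa = (P0 - Pe) / (1 - Pe)

A closed-set classifier (one that never predicts UNKNOWN) always has
recall 1, so its F1 is fixed by the test composition alone: with k known
and u unknown test samples, F1 = 2k / (2k + u).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import UNKNOWN_LABEL

__all__ = [
    "DetectionCounts",
    "OpenSetMetrics",
    "count_detection",
    "precision_recall_f1",
    "confusion_matrix",
    "overall_accuracy",
    "kappa",
    "kappa_ku",
    "evaluate_openset",
    "metrics_to_json",
]


@dataclass
class DetectionCounts:
    """Known-accepted / known-rejected / unknown-accepted counts."""

    num_k_right: int
    num_k_error: int
    num_uk_error: int

    def __post_init__(self) -> None:
        if min(self.num_k_right, self.num_k_error, self.num_uk_error) < 0:
            raise ValueError("detection counts must be nonnegative")


@dataclass
class OpenSetMetrics:
    counts: DetectionCounts
    precision: float
    recall: float
    f1: float
    p0: float
    pe: float
    kappa: float
    labels: list[str]
    confusion: np.ndarray


def count_detection(truth_known, predicted_labels) -> DetectionCounts:
    """Tally detection outcomes.

    ``truth_known[i]`` is True when sample i belongs to a known class.  A
    known sample counts as right when predicted as *any* known label
    (species mistakes are scored by P0/kappa, not by detection F1).
    """
    truth_known = list(truth_known)
    predicted_labels = list(predicted_labels)
    if len(truth_known) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(truth_known)} truths, "
            f"{len(predicted_labels)} predictions"
        )
    kr = ke = uke = 0
    for known, pred in zip(truth_known, predicted_labels):
        accepted = pred != UNKNOWN_LABEL
        if known:
            if accepted:
                kr += 1
            else:
                ke += 1
        elif accepted:
            uke += 1
    return DetectionCounts(kr, ke, uke)


def precision_recall_f1(c: DetectionCounts) -> tuple[float, float, float]:
    """Detection precision, recall and F1; every 0/0 is defined as 0."""
    p_den = c.num_k_right + c.num_uk_error
    r_den = c.num_k_right + c.num_k_error
    precision = c.num_k_right / p_den if p_den else 0.0
    recall = c.num_k_right / r_den if r_den else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def confusion_matrix(truth_labels, predicted_labels, known_labels) -> tuple[list[str], np.ndarray]:
    """(K+1) x (K+1) confusion matrix, rows = truth, columns = prediction.

    Truth labels outside ``known_labels`` collapse into the UNKNOWN row;
    predictions are either a known label or UNKNOWN.
    """
    truth_labels = list(truth_labels)
    predicted_labels = list(predicted_labels)
    if len(truth_labels) != len(predicted_labels):
        raise ValueError("truth/prediction length mismatch")
    known = list(known_labels)
    axis = known + [UNKNOWN_LABEL]
    index = {lab: i for i, lab in enumerate(axis)}
    M = np.zeros((len(axis), len(axis)), dtype=int)
    for t, p in zip(truth_labels, predicted_labels):
        ti = index.get(t, index[UNKNOWN_LABEL])
        if p not in index:
            raise ValueError(f"prediction {p!r} is neither a known label nor UNKNOWN")
        M[ti, index[p]] += 1
    return axis, M


def overall_accuracy(confusion: np.ndarray) -> float:
    """P0 = trace / n: exact species for knowns, UNKNOWN for unknowns."""
    confusion = np.asarray(confusion)
    n = confusion.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / n)


def kappa(confusion: np.ndarray) -> tuple[float, float]:
    """Chance agreement Pe from the marginals and Cohen's kappa.

    The degenerate Pe = 1 case (all mass in one matched marginal pair) is
    defined as kappa = 1 when agreement is perfect and 0 otherwise.
    """
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p0 = overall_accuracy(confusion)
    pe = float(confusion.sum(axis=1) @ confusion.sum(axis=0) / (n * n))
    if abs(1.0 - pe) < 1e-15:
        return pe, 1.0 if abs(p0 - 1.0) < 1e-15 else 0.0
    return pe, float((p0 - pe) / (1.0 - pe))


def kappa_ku(truth_labels, predicted_labels, known_labels, unknown_labels) -> tuple[float, float]:
    """Kappa under the K+U class-space reading.

    Rows are the individual truth species (known and unknown); predictions
    can only name known species or UNKNOWN, so every unknown species has a
    zero predicted-count marginal and contributes nothing to Pe.  P0 is
    unchanged (UNKNOWN is correct for any unknown species).  Offered for
    comparison; the collapsed K+1 convention is the default elsewhere.
    """
    truth_labels = list(truth_labels)
    predicted_labels = list(predicted_labels)
    n = len(truth_labels)
    if n == 0:
        raise ValueError("no samples")
    known = set(known_labels)
    correct = sum(
        1
        for t, p in zip(truth_labels, predicted_labels)
        if (t in known and p == t) or (t not in known and p == UNKNOWN_LABEL)
    )
    p0 = correct / n
    pe = 0.0
    for lab in known_labels:
        numit = sum(1 for t in truth_labels if t == lab)
        numip = sum(1 for p in predicted_labels if p == lab)
        pe += numit * numip / (n * n)
    if abs(1.0 - pe) < 1e-15:
        return pe, 1.0 if abs(p0 - 1.0) < 1e-15 else 0.0
    return pe, (p0 - pe) / (1.0 - pe)


def evaluate_openset(truth_labels, predicted_labels, known_labels) -> OpenSetMetrics:
    """Full open-set report: detection F1 plus (K+1)-class P0/Pe/kappa."""
    known = list(known_labels)
    known_set = set(known)
    truth_known = [t in known_set for t in truth_labels]
    counts = count_detection(truth_known, predicted_labels)
    precision, recall, f1 = precision_recall_f1(counts)
    axis, M = confusion_matrix(truth_labels, predicted_labels, known)
    p0 = overall_accuracy(M)
    pe, kap = kappa(M)
    return OpenSetMetrics(
        counts=counts,
        precision=precision,
        recall=recall,
        f1=f1,
        p0=p0,
        pe=pe,
        kappa=kap,
        labels=axis,
        confusion=M,
    )


def metrics_to_json(m: OpenSetMetrics) -> str:
    return json.dumps(
        {
            "counts": {
                "num_k_right": m.counts.num_k_right,
                "num_k_error": m.counts.num_k_error,
                "num_uk_error": m.counts.num_uk_error,
            },
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
            "p0": m.p0,
            "pe": m.pe,
            "kappa": m.kappa,
            "labels": m.labels,
            "confusion": m.confusion.tolist(),
        },
        indent=1,
    )
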