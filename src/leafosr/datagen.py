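"""Open-set split protocol, synthetic embedding generator and LBP features.

The split builder implements the hold-out protocol used throughout: pick
known and unknown class sets, keep a fixed share (default 8:2) of each
known class for training, and send everything else — the known remainder
plus every unknown-class sample — to the test set.  With 15 classes of 75
samples this yields 300 train / 825 test for 5 known classes and
600 / 525 for 10.

The synthetic generator emulates the geometry of CNN embedding vectors:
each class is an isotropic Gaussian cluster around a center drawn
uniformly on a hypersphere, so class separation is controlled by the
sphere radius (``center_scale``) relative to the within-class noise.

The LBP extractor is the classic radius-1, 8-neighbor local binary
pattern: each interior pixel is encoded by comparing its 8 neighbors to
it (ties count as >=), clockwise from the top-left with the first
neighbor in the most significant bit, and the image is summarized by the
normalized 256-bin histogram of codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureTable

__all__ = [
    "OpenSetSplit",
    "SyntheticConfig",
    "build_split",
    "simulate_features",
    "lbp_histogram",
]


@dataclass
class OpenSetSplit:
    train: FeatureTable
    test: FeatureTable
    known_labels: list[str]
    unknown_labels: list[str]
    seed: int


@dataclass
class SyntheticConfig:
    """Conditions for the synthetic embedding benchmark.

    Defaults mirror the 15-species x 75-image shape of a typical leaf
    dataset at desk scale: 5 known + 10 unknown classes, 75 samples per
    class, 50-dimensional features (the real embeddings are 1000-D but the
    geometry is the same), class centers on a radius-8 hypersphere with
    unit within-class noise.
    """

    n_known: int = 5
    n_unknown: int = 10
    per_class: int = 75
    dim: int = 50
    center_scale: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_known, self.per_class, self.dim) < 1 or self.n_unknown < 0:
            raise ValueError("class/sample/dimension counts must be >= 1")
        if self.center_scale <= 0 or self.noise_sd <= 0:
            raise ValueError("center_scale and noise_sd must be positive")


def build_split(
    table: FeatureTable,
    known,
    unknown,
    holdout: float = 0.8,
    seed: int = 0,
) -> OpenSetSplit:
    """Partition a labeled table into an open-set train/test pair.

    Per known class, ``floor(holdout * count)`` rows (seeded shuffle) go
    to training and the rest to test; all unknown-class rows go to test.
    """
    known = list(known)
    unknown = list(unknown)
    if set(known) & set(unknown):
        raise ValueError("known and unknown label sets must be disjoint")
    if not 0.0 < holdout < 1.0:
        raise ValueError(f"holdout ratio must be in (0, 1), got {holdout}")
    present = set(table.labels)
    for lab in known + unknown:
        if lab not in present:
            raise ValueError(f"label {lab!r} not present in the table")
    labels = np.asarray(table.labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in known:
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        cut = int(np.floor(holdout * len(idx)))
        train_idx.extend(idx[:cut].tolist())
        test_idx.extend(idx[cut:].tolist())
    for lab in unknown:
        test_idx.extend(np.flatnonzero(labels == lab).tolist())
    return OpenSetSplit(
        train=table.subset(sorted(train_idx)),
        test=table.subset(sorted(test_idx)),
        known_labels=known,
        unknown_labels=unknown,
        seed=seed,
    )


def simulate_features(cfg: SyntheticConfig) -> FeatureTable:
    """Gaussian class clusters with centers uniform on a hypersphere.

    Known-pool classes are labeled ``K01, K02, ...`` and unknown-pool
    classes ``U01, U02, ...``; sample ids are ``<label>-<index>``.
    Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_classes = cfg.n_known + cfg.n_unknown
    centers = rng.standard_normal((n_classes, cfg.dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= cfg.center_scale
    labels_pool = [f"K{i + 1:02d}" for i in range(cfg.n_known)] + [
        f"U{i + 1:02d}" for i in range(cfg.n_unknown)
    ]
    ids: list[str] = []
    labels: list[str] = []
    rows = []
    for c, lab in enumerate(labels_pool):
        noise = rng.standard_normal((cfg.per_class, cfg.dim)) * cfg.noise_sd
        rows.append(centers[c] + noise)
        ids.extend(f"{lab}-{j + 1:03d}" for j in range(cfg.per_class))
        labels.extend([lab] * cfg.per_class)
    return FeatureTable(ids=ids, labels=labels, X=np.vstack(rows))


# 8 neighbors clockwise from the top-left corner; the first entry maps to
# the most significant bit of the code.
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
]


def _uniform_code_map() -> np.ndarray:
    """Map each 8-bit code to a bin: 58 uniform patterns + 1 catch-all."""
    mapping = np.full(256, 58, dtype=int)
    nxt = 0
    for code in range(256):
        bits = [(code >> (7 - b)) & 1 for b in range(8)]
        transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
        if transitions <= 2:
            mapping[code] = nxt
            nxt += 1
    assert nxt == 58
    return mapping


_UNIFORM_MAP = _uniform_code_map()


def lbp_histogram(img, uniform: bool = False) -> np.ndarray:
    """Normalized local-binary-pattern histogram of a grayscale image.

    Bit b of a pixel's code is set iff the b-th neighbor (clockwise from
    top-left) is >= the center; border pixels are excluded.  Returns 256
    bins by default, or the 59-bin uniform-pattern variant when
    ``uniform`` is True.  The histogram sums to 1.
    """
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got shape {img.shape}")
    center = img[1:-1, 1:-1].astype(np.int64)
    codes = np.zeros_like(center)
    h, w = img.shape
    for bit, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        nb = img[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc].astype(np.int64)
        codes = (codes << 1) | (nb >= center)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    if uniform:
        out = np.zeros(59)
        np.add.at(out, _UNIFORM_MAP, hist)
        hist = out
    return hist / hist.sum()
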