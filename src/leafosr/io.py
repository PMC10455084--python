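"""Feature-table, image and configuration file I/O.

Feature files are plain comma-delimited UTF-8 text with a header row
``id,label,f1,...,fd``; features are written with 17 significant digits
so a write/read round-trip reproduces every float bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import FeatureTable

__all__ = [
    "read_features",
    "write_features",
    "read_gray_image",
    "read_config",
    "write_config",
]


def read_features(path) -> FeatureTable:
    """Read a feature table from CSV, validating the schema."""
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str, 1: str}, float_precision="round_trip")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["id", "label"]:
        raise ValueError(
            f"{path}: expected header 'id,label,f1,...', got {list(df.columns)[:4]}"
        )
    feat_cols = df.columns[2:]
    ids = df["id"].tolist()
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        rows = [i + 2 for i in df.index[df["id"].duplicated()][:3]]
        raise ValueError(f"{path}: duplicate sample ids {dupes[:3]} (rows {rows})")
    try:
        X = df[feat_cols].astype(float).to_numpy()
    except (ValueError, TypeError):
        for i, row in df[feat_cols].iterrows():
            try:
                row.astype(float)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: non-numeric feature value at row {i + 2}")
        raise
    if not np.all(np.isfinite(X)):
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise ValueError(f"{path}: non-finite feature value at row {bad + 2}")
    return FeatureTable(ids=ids, labels=df["label"].tolist(), X=X)


def write_features(table: FeatureTable, path) -> None:
    """Write a feature table as CSV with round-trip float precision."""
    path = Path(path)
    df = pd.DataFrame(table.X, columns=[f"f{j + 1}" for j in range(table.d)])
    df.insert(0, "label", table.labels)
    df.insert(0, "id", table.ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_gray_image(path) -> np.ndarray:
    """Load a PNG/PGM image as an 8-bit grayscale array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` experiment configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{k} = {v}\n" for k, v in cfg.items()), encoding="utf-8"
    )
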