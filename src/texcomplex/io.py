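"""File formats: images in/out, rank CSVs, feature tables.

Rank CSV schema: header ``observer_id,replicate,<sample-id>,...``;
one row per observer session; cells are 1-based positions.  An
optional leading ``attribute`` column tags the judged attribute.
Feature CSVs are the long (tidy) table written by the pipeline:
``sample_id,space,channel,feature,params,value``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .psychophysics import RankMatrix

logger = logging.getLogger("texcomplex")

IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

FEATURE_COLUMNS = ("sample_id", "space", "channel", "feature", "params", "value")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF into an H x W x 3 float array in [0, 1].

    8- and 16-bit integer images are scaled by their type maximum;
    grayscale images are replicated to three channels.
    """
    arr = np.asarray(Image.open(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, rgb: np.ndarray) -> None:
    """Write an sRGB array in [0, 1] as an 8-bit PNG/TIFF."""
    arr = (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def write_channel_tiff(path: str | Path, values: np.ndarray) -> None:
    """Debug export of a single channel as float32 TIFF."""
    Image.fromarray(np.asarray(values, dtype=np.float32)).save(path)


def read_images(directory: str | Path) -> dict[str, np.ndarray]:
    """All images in a directory, keyed by file stem; non-images are skipped."""
    directory = Path(directory)
    out: dict[str, np.ndarray] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix.lower() not in IMAGE_SUFFIXES:
            if path.is_file():
                logger.warning("skipping non-image file %s", path.name)
            continue
        out[path.stem] = read_image(path)
    return out


def read_rank_csv(path: str | Path) -> RankMatrix:
    """Parse one rank matrix, validating every cell with its location."""
    df = pd.read_csv(path)
    attribute = ""
    if "attribute" in df.columns:
        labels = df.pop("attribute").unique()
        if len(labels) != 1:
            raise ValueError(f"{path}: expected a single attribute, found {list(labels)}")
        attribute = str(labels[0])
    for col in ("observer_id", "replicate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("observer_id", "replicate")]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    T = len(sample_cols)
    ranks = np.empty((len(df), T), dtype=int)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, col in enumerate(sample_cols):
            v = row[col]
            if not float(v).is_integer() or not 1 <= int(v) <= T:
                raise ValueError(
                    f"{path}: invalid rank {v!r} at row {i + 2}, column {col!r} (must be 1..{T})"
                )
            ranks[i, j] = int(v)
    return RankMatrix(
        ranks,
        attribute=attribute,
        observers=df["observer_id"].tolist(),
        replicates=df["replicate"].tolist(),
        sample_ids=sample_cols,
    )


def write_rank_csv(path: str | Path, rm: RankMatrix) -> None:
    df = pd.DataFrame(rm.ranks, columns=rm.sample_ids)
    df.insert(0, "replicate", rm.replicates)
    df.insert(0, "observer_id", rm.observers)
    if rm.attribute:
        df.insert(0, "attribute", rm.attribute)
    df.to_csv(path, index=False)


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    table[list(FEATURE_COLUMNS)].to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
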