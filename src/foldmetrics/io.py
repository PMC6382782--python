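"""File I/O: single-channel TIFF images/masks, cohort CSV, report output.

Images are 8-bit single-channel TIFF (the pipeline's native format);
16-bit input is linearly rescaled to 8-bit with a warning, or rejected
under ``strict=True``.  Masks are written as 0/255 8-bit TIFF.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_cohort_csv",
    "write_report",
]

COHORT_REQUIRED = ("eye_id", "timepoint", "mv", "mh")


def read_image(path, strict: bool = False) -> np.ndarray:
    """Read a single-channel TIFF as a uint8 array.

    Multi-channel or non-TIFF input raises a format error.  16-bit images
    are rescaled so their maximum maps to 255 (warned), unless ``strict``.
    """
    path = Path(path)
    try:
        img = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types on bad magic
        raise ValueError(f"{path}: not a readable TIFF ({exc})") from exc
    if img.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img
    if img.dtype == np.uint16:
        if strict:
            raise ValueError(f"{path}: 16-bit input rejected under strict mode")
        warnings.warn(f"{path}: 16-bit TIFF rescaled to 8-bit", stacklevel=2)
        top = int(img.max())
        if top == 0:
            return np.zeros(img.shape, dtype=np.uint8)
        return np.floor(img.astype(np.float64) * (255.0 / top) + 0.5).astype(np.uint8)
    raise ValueError(f"{path}: unsupported dtype {img.dtype}")


def write_image(img: np.ndarray, path) -> None:
    """Write a uint8 image as single-channel TIFF (lossless round-trip)."""
    img = np.asarray(img)
    if img.ndim != 2 or img.dtype != np.uint8:
        raise ValueError("write_image expects a 2-D uint8 array")
    tifffile.imwrite(Path(path), img)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as 0/255 8-bit TIFF."""
    mask = np.asarray(mask, dtype=bool)
    write_image((mask * np.uint8(255)), path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask TIFF back to boolean."""
    return read_image(path) > 0


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a longitudinal cohort CSV, validating the schema.

    Requires ``eye_id, timepoint, mv, mh`` columns; ``mean_mcharts`` is
    derived if absent.  Missing columns raise a schema error naming them.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing column(s): {', '.join(missing)}")
    if "mean_mcharts" not in df.columns:
        df["mean_mcharts"] = (df["mv"] + df["mh"]) / 2.0
    return df


def write_report(report, path) -> None:
    """Write a StatsReport as JSON (tables in split-record form) + CSVs.

    ``path`` is the JSON file; sibling CSVs are written next to it with
    suffixes ``_friedman.csv``, ``_pairwise.csv``, ``_groups.csv``,
    ``_spearman.csv``.
    """
    path = Path(path)
    tables = {
        "friedman": report.friedman,
        "pairwise": report.pairwise,
        "groups": report.group_comparisons,
        "spearman": report.spearman,
    }
    payload = {"alpha": report.alpha}
    for name, df in tables.items():
        payload[name] = df.to_dict(orient="records")
        df.to_csv(path.with_name(path.stem + f"_{name}.csv"), index=False)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
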