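"""Readers and writers: manifests, lesion images/masks, feature tables,
frozen feature sets.

File conventions: lesion images are 16-bit grayscale TIFF (8/16-bit PNG is
also accepted), masks are 8-bit PNG with foreground 255, manifests and
feature tables are CSV, frozen feature sets are JSON.  All writers are
deterministic: stable row/column order and fixed float formatting (12
significant digits, which makes the CSV round trip lossless well beyond
the reproducibility we rely on).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .registry import all_names

__all__ = [
    "MANIFEST_COLUMNS",
    "read_manifest",
    "write_manifest",
    "read_lesion",
    "write_lesion",
    "read_feature_table",
    "write_feature_table",
    "read_feature_set",
    "write_feature_set",
]

MANIFEST_COLUMNS = ["sample_id", "image", "mask", "er", "pr", "her2", "subtype"]
RECEPTOR_VALUES = {"pos", "neg", "unknown"}
SUBTYPE_VALUES = {"LuminalA", "LuminalB", "HER2E", "TN", "unknown"}
_SUBTYPE_CANON = {s.lower(): s for s in SUBTYPE_VALUES}

MIN_MASK_PIXELS = 16  # lesion-size floor; tiny ROIs carry no usable texture


def _norm_receptor(value, row_id: str) -> str:
    s = str(value).strip().lower()
    if s in ("", "nan", "none"):
        return "unknown"
    if s in RECEPTOR_VALUES:
        return s
    if s in ("positive", "+", "1"):
        return "pos"
    if s in ("negative", "-", "0"):
        return "neg"
    raise ValueError(f"manifest row {row_id!r}: bad receptor status {value!r}")


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    Receptor strings are normalized case-insensitively to pos/neg/unknown;
    every row must carry a subtype label and/or a full receptor triplet.
    Referenced image/mask paths are resolved relative to the manifest
    location and checked for existence unless ``check_files=False``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id in manifest: {sorted(set(dupes))}")
    base = path.parent
    for i, rec in df.iterrows():
        sid = rec["sample_id"]
        for col in ("er", "pr", "her2"):
            df.at[i, col] = _norm_receptor(rec[col], sid)
        sub = str(rec["subtype"]).strip()
        df.at[i, "subtype"] = _SUBTYPE_CANON.get(sub.lower(), sub) if sub else "unknown"
        if df.at[i, "subtype"] == "unknown" and "unknown" in (
            df.at[i, "er"],
            df.at[i, "pr"],
            df.at[i, "her2"],
        ):
            raise ValueError(
                f"manifest row {sid!r}: needs a subtype or a complete receptor triplet"
            )
        for col in ("image", "mask"):
            p = Path(rec[col])
            if not p.is_absolute():
                p = base / p
            df.at[i, col] = str(p)
            if check_files and not p.exists():
                raise ValueError(f"manifest row {sid!r}: file not found: {p}")
    return df.reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def _read_gray(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:  # tolerate an RGB(A) image with identical channels
        arr = arr[..., 0]
    return arr


def read_lesion(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load a lesion image and its binary mask (thresholded at > 0)."""
    image = _read_gray(image_path).astype(np.int64)
    mask = _read_gray(mask_path) > 0
    if image.shape != mask.shape:
        raise ValueError(
            f"image {image.shape} and mask {mask.shape} dimensions differ "
            f"({image_path} / {mask_path})"
        )
    n = int(mask.sum())
    if n < MIN_MASK_PIXELS:
        raise ValueError(f"mask {mask_path} has {n} pixels (< {MIN_MASK_PIXELS})")
    return image, mask


def write_lesion(image: np.ndarray, mask: np.ndarray, image_path, mask_path) -> None:
    """Write a 16-bit TIFF image and an 8-bit PNG mask (foreground 255)."""
    tifffile.imwrite(image_path, np.asarray(image, dtype=np.uint16))
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(mask_path)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table CSV in registry column order.

    Refuses tables with NaN/Inf values: extraction guarantees finiteness,
    so a non-finite value indicates an upstream defect.
    """
    cols = ["sample_id", *all_names()]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing[:5]}...")
    df = df[cols]
    numeric = df.drop(columns="sample_id").to_numpy(dtype=np.float64)
    if not np.isfinite(numeric).all():
        raise ValueError("feature table contains non-finite values; refusing to write")
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV and validate its columns against the registry."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("feature table lacks a sample_id column")
    known = set(all_names())
    unknown = [c for c in df.columns if c != "sample_id" and c not in known]
    if unknown:
        raise ValueError(f"unknown feature column(s): {unknown[:5]}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_feature_set(featureset: dict, path) -> None:
    """Persist a selected feature set (criterion, k, names, scores) as JSON."""
    with open(path, "w") as fh:
        json.dump(featureset, fh, indent=1, sort_keys=True)


def read_feature_set(path) -> dict:
    with open(path) as fh:
        fs = json.load(fh)
    for key in ("criterion", "k", "features"):
        if key not in fs:
            raise ValueError(f"feature-set file {path} lacks {key!r}")
    return fs
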