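"""Sliding-window per-pixel feature maps, for illustration only.

A feature map evaluates one texture feature on a square window around each
masked pixel (window intersected with the mask), using the normalization
parameters of the *full* ROI so that map contrast reflects texture rather
than local renormalization.  Geometry features are global by nature and
cannot be mapped.  Maps are excluded from classification.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .prep import QuantizedROI, compute_norm_params, quantize_roi
from .registry import family_of, parse_com_name
from .texture import (
    arm_features,
    com_features,
    com_matrix,
    gra_features,
    his_features,
    rlm_features,
    wav_features,
)

__all__ = ["FeatureMap", "compute_feature_map", "render_overlay"]

_MIN_WINDOW_PIXELS = 16


class FeatureMap:
    """Per-masked-pixel values of one feature; NaN where undefined."""

    def __init__(self, values: np.ndarray, mask: np.ndarray, feature_name: str, window: int):
        self.values = values
        self.mask = mask
        self.feature_name = feature_name
        self.window = window

    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)


def _single_feature(q: QuantizedROI, name: str) -> float:
    fam = family_of(name)
    if fam == "HIS":
        return his_features(q)[name]
    if fam == "COM":
        dx, dy, _ = parse_com_name(name)
        return com_features(com_matrix(q, (dx, dy)))[name.split(")")[-1]]
    if fam == "RLM":
        direction = name.split("_")[0]
        return rlm_features(q, direction)[name]
    if fam == "GRA":
        return gra_features(q)[name]
    if fam == "ARM":
        return arm_features(q).as_features()[name]
    if fam == "WAV":
        return wav_features(q)[name]
    raise ValueError(f"{name}: global feature, cannot be mapped")


def compute_feature_map(image, mask, feature_name: str, window: int = 15) -> FeatureMap:
    """Evaluate one registry feature on a sliding window over the lesion.

    Windows containing fewer than 16 masked pixels yield a missing value
    (NaN).  GEO features raise, since shape is a property of the whole
    lesion outline.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    fam = family_of(feature_name)  # raises on non-registry names
    if fam == "GEO":
        raise ValueError(f"{feature_name}: global feature, no sliding-window map")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    params = compute_norm_params(image, mask)
    # quantize the whole frame once with the global ROI parameters
    full = quantize_roi(image, np.ones_like(mask), params)
    half = window // 2
    values = np.full(image.shape, np.nan)
    rr, cc = np.nonzero(mask)
    h, w = mask.shape
    for r, c in zip(rr, cc):
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        sub_mask = mask[r0:r1, c0:c1]
        if sub_mask.sum() < _MIN_WINDOW_PIXELS:
            continue
        sub_levels = np.where(sub_mask, full.levels[r0:r1, c0:c1], 0)
        q = QuantizedROI(levels=sub_levels, mask=sub_mask, params=params)
        values[r, c] = _single_feature(q, feature_name)
    return FeatureMap(values=values, mask=mask, feature_name=feature_name, window=window)


def render_overlay(fmap: FeatureMap, image, out_path, cmap: str = "viridis") -> None:
    """Write a PNG with the color-coded map over the grayscale image.

    The color scale spans the min-max of the defined map values; pixels
    outside the map keep their grayscale value.  Output bytes are a pure
    function of the inputs.
    """
    defined = fmap.defined()
    if not defined.any():
        raise ValueError("feature map has no defined values")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    gray = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    vals = fmap.values[defined]
    vmin, vmax = vals.min(), vals.max()
    t = (fmap.values - vmin) / (vmax - vmin) if vmax > vmin else np.zeros_like(fmap.values)
    colored = colormaps[cmap](np.nan_to_num(t))[..., :3]
    rgb[defined] = colored[defined]
    Image.fromarray((rgb * 255).round().astype(np.uint8)).save(out_path)
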