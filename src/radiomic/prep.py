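"""ROI gray-level normalization and quantization.

Each lesion ROI is normalized independently before any texture feature is
computed: intensities are limited to mu +/- 3 sigma (mu, sigma = mean and
population standard deviation of the masked pixels) and then linearly
binned into ``n_levels`` equal-width gray levels 1..n_levels.  This removes
per-scan brightness/contrast offsets so that texture features compare
across acquisitions.  Out-of-range pixels are clipped into the extreme
bins (not excluded), keeping the pixel support of the ROI intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizationParams", "QuantizedROI", "compute_norm_params", "quantize_roi"]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-ROI normalization window mu +/- 3 sigma and gray-level count."""

    mu: float
    sigma: float
    n_levels: int = 64

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")

    @property
    def clip_low(self) -> float:
        return self.mu - 3.0 * self.sigma

    @property
    def clip_high(self) -> float:
        return self.mu + 3.0 * self.sigma


@dataclass(frozen=True)
class QuantizedROI:
    """Gray-level-quantized lesion: levels in 1..n_levels on masked pixels.

    ``levels`` is a full-frame integer array holding 0 outside the mask;
    every masked pixel carries a level in [1, n_levels].  This object is
    the sole substrate of all texture-feature families.
    """

    levels: np.ndarray
    mask: np.ndarray
    params: NormalizationParams

    def __post_init__(self):
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask shapes differ")

    @property
    def n_levels(self) -> int:
        return self.params.n_levels

    def masked_levels(self) -> np.ndarray:
        """1-D array of levels of the masked pixels (row-major order)."""
        return self.levels[self.mask]

    @classmethod
    def from_levels(cls, levels, n_levels: int, mask=None) -> "QuantizedROI":
        """Wrap a pre-quantized level array (levels already in 1..n_levels).

        Intended for toy inputs and oracles where the gray levels are given
        directly rather than derived from raw intensities.
        """
        levels = np.asarray(levels, dtype=np.int32)
        if mask is None:
            mask = levels > 0
        mask = np.asarray(mask, dtype=bool)
        lv = np.where(mask, levels, 0)
        if mask.any() and (lv[mask].min() < 1 or lv[mask].max() > n_levels):
            raise ValueError("levels outside [1, n_levels]")
        params = NormalizationParams(mu=0.0, sigma=0.0, n_levels=n_levels)
        return cls(levels=lv, mask=mask, params=params)


def compute_norm_params(image, mask, n_levels: int = 64) -> NormalizationParams:
    """Mean and population SD of the masked intensities."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = image[mask]
    return NormalizationParams(mu=float(vals.mean()), sigma=float(vals.std()), n_levels=n_levels)


def quantize_roi(image, mask, params: NormalizationParams) -> QuantizedROI:
    """Clip masked intensities to mu +/- 3 sigma and bin into 1..n_levels.

    A zero-variance ROI maps every masked pixel to the middle level
    ceil(n_levels / 2).  The standardized intensity is rounded at 1e-9
    before binning so that an exact affine rescaling of the raw image
    (which the normalization is designed to cancel) cannot flip pixels
    across bin edges through floating-point jitter.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    n = params.n_levels
    levels = np.zeros(image.shape, dtype=np.int32)
    if params.sigma == 0.0:
        levels[mask] = int(np.ceil(n / 2))
        return QuantizedROI(levels=levels, mask=mask, params=params)
    z = (image[mask] - params.mu) / params.sigma
    z = np.clip(np.round(z, 9), -3.0, 3.0)
    t = (z + 3.0) / 6.0  # in [0, 1]
    lv = np.floor(t * n).astype(np.int32) + 1
    np.clip(lv, 1, n, out=lv)
    levels[mask] = lv
    return QuantizedROI(levels=levels, mask=mask, params=params)
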