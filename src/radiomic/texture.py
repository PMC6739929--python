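"""Texture feature families computed on a quantized lesion ROI.

Implements the five texture families of the MaZda feature set plus the
Haar-wavelet energies, all on the gray-level-quantized ROI produced by
:mod:`radiomic.prep`:

* HIS  — first-order histogram statistics of the masked levels (9).
* COM  — Haralick statistics of symmetric gray-level co-occurrence
  matrices at 20 pixel offsets (4 orientations x distances 1..5; 220).
* RLM  — gray-level run-length statistics in 4 directions (20).
* GRA  — absolute gradient statistics on interior pixels (5).
* ARM  — causal 2-D autoregressive model parameters Teta1..Teta4, Sigma (5).
* WAV  — orthonormal Haar subband energies at 5 scales (20).

All entropies use the natural logarithm with the convention 0 * log 0 = 0.
Degenerate inputs (no valid pixel pair, no interior pixel, too few AR
training pixels) yield zeros plus a logged warning, never NaN, so that
downstream feature selection is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .prep import QuantizedROI
from .registry import (
    ARM_NAMES,
    COM_OFFSETS,
    COM_STATS,
    GRA_NAMES,
    HIS_NAMES,
    RLM_DIRECTIONS,
    RLM_STATS,
    com_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "COMatrix",
    "ARModelFit",
    "his_features",
    "com_matrix",
    "com_features",
    "rlm_runs",
    "rlm_features",
    "gra_features",
    "arm_features",
    "wav_features",
    "texture_features",
]


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness, excess kurtosis.

    Skewness and kurtosis of a zero-variance sample are defined as 0.
    """
    values = np.asarray(values, dtype=np.float64)
    mean = float(values.mean())
    var = float(values.var())
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    d = values - mean
    skew = float((d**3).mean() / var**1.5)
    kurt = float((d**4).mean() / var**2 - 3.0)
    return mean, var, skew, kurt


def his_features(q: QuantizedROI) -> dict[str, float]:
    """First-order histogram statistics of the masked gray levels."""
    lv = q.masked_levels().astype(np.float64)
    mean, var, skew, kurt = _moments(lv)
    p1, p10, p50, p90, p99 = np.percentile(lv, [1, 10, 50, 90, 99])
    vals = (mean, var, skew, kurt, p1, p10, p50, p90, p99)
    return dict(zip(HIS_NAMES, (float(v) for v in vals)))


# ---------------------------------------------------------------------------
# Co-occurrence matrix (COM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class COMatrix:
    """Symmetric gray-level co-occurrence probability matrix at one offset."""

    offset: tuple[int, int]
    p: np.ndarray
    degenerate: bool = False


def com_matrix(q: QuantizedROI, offset: tuple[int, int]) -> COMatrix:
    """Co-occurrence matrix for pixel pairs (s, s + (dx, dy)), symmetrized.

    dx is the column offset, dy the row offset (y axis points down).  Each
    unordered pair with both pixels masked is counted in both directions;
    counts are normalized to probabilities.  If no valid pair exists, the
    matrix is all-zero and flagged degenerate.
    """
    dx, dy = offset
    n = q.n_levels
    lv, mask = q.levels, q.mask
    h, w = lv.shape
    counts = np.zeros((n, n), dtype=np.int64)

    r0s, r0e = max(0, -dy), min(h, h - dy)
    c0s, c0e = max(0, -dx), min(w, w - dx)
    if r0s < r0e and c0s < c0e:
        a = lv[r0s:r0e, c0s:c0e]
        b = lv[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
        valid = mask[r0s:r0e, c0s:c0e] & mask[r0s + dy : r0e + dy, c0s + dx : c0e + dx]
        if valid.any():
            i = a[valid] - 1
            j = b[valid] - 1
            flat = np.bincount(i * n + j, minlength=n * n)
            counts = flat.reshape(n, n)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return COMatrix(offset=offset, p=np.zeros((n, n)), degenerate=True)
    return COMatrix(offset=offset, p=counts / total, degenerate=False)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with 0 log 0 = 0."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def com_features(m: COMatrix) -> dict[str, float]:
    """Eleven Haralick-type statistics of one co-occurrence matrix.

    Gray levels are indexed 1..n.  Correlation of a single-level matrix
    (zero marginal variance) is defined as 0.
    """
    if m.degenerate:
        return {s: 0.0 for s in COM_STATS}
    p = m.p
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # marginal (symmetric, px == py)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    # distributions of i+j (2..2n) and |i-j| (0..n-1)
    ksum = np.arange(2, 2 * n + 1, dtype=np.float64)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel() - 2, p.ravel())
    kdif = np.arange(0, n, dtype=np.float64)
    p_dif = np.zeros(n)
    np.add.at(p_dif, np.abs(ii - jj).astype(np.int64).ravel(), p.ravel())

    ang_sc_mom = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var > 0:
        correlat = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        correlat = 0.0
    sum_of_sqs = float((((ii - mu) ** 2) * p).sum())
    inv_df_mom = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_averg = float((ksum * p_sum).sum())
    sum_varnc = float((((ksum - sum_averg) ** 2) * p_sum).sum())
    sum_entrp = _entropy(p_sum)
    entropy = _entropy(p)
    mu_dif = float((kdif * p_dif).sum())
    dif_varnc = float((((kdif - mu_dif) ** 2) * p_dif).sum())
    dif_entrp = _entropy(p_dif)

    vals = (
        ang_sc_mom,
        contrast,
        correlat,
        sum_of_sqs,
        inv_df_mom,
        sum_averg,
        sum_varnc,
        sum_entrp,
        entropy,
        dif_varnc,
        dif_entrp,
    )
    return dict(zip(COM_STATS, vals))


# ---------------------------------------------------------------------------
# Run-length matrix (RLM)
# ---------------------------------------------------------------------------

#: step (dy, dx) per direction; runs are maximal constant-level segments
#: along masked collinear pixels.
_RLM_STEPS = {
    "Horzl": (0, 1),
    "Vertl": (1, 0),
    "45dgr": (-1, 1),  # up-right (y axis points down)
    "135dr": (1, 1),  # down-right
}


def _direction_lines(q: QuantizedROI, direction: str):
    """Yield (levels, mask) 1-D arrays for every scan line of a direction."""
    lv, mask = q.levels, q.mask
    if direction == "Horzl":
        for r in range(lv.shape[0]):
            yield lv[r], mask[r]
    elif direction == "Vertl":
        for c in range(lv.shape[1]):
            yield lv[:, c], mask[:, c]
    elif direction == "135dr":
        h, w = lv.shape
        for off in range(-h + 1, w):
            yield np.diagonal(lv, off), np.diagonal(mask, off)
    elif direction == "45dgr":
        flv, fmask = np.flipud(lv), np.flipud(mask)
        h, w = lv.shape
        for off in range(-h + 1, w):
            yield np.diagonal(flv, off), np.diagonal(fmask, off)
    else:
        raise ValueError(f"unknown run direction: {direction!r}")


def rlm_runs(q: QuantizedROI, direction: str) -> tuple[dict[tuple[int, int], int], int]:
    """Run counts r(gray, length) and the number of masked pixels traversed."""
    runs: dict[tuple[int, int], int] = {}
    traversed = 0
    for lv, mask in _direction_lines(q, direction):
        traversed += int(mask.sum())
        m = int(len(lv))
        idx = 0
        while idx < m:
            if not mask[idx]:
                idx += 1
                continue
            g = int(lv[idx])
            length = 1
            while idx + length < m and mask[idx + length] and int(lv[idx + length]) == g:
                length += 1
            runs[(g, length)] = runs.get((g, length), 0) + 1
            idx += length
    return runs, traversed


def rlm_features(q: QuantizedROI, direction: str) -> dict[str, float]:
    """Five run-length statistics for one direction.

    ShrtREmp = sum r/l^2 / sum r; LngREmph = sum r*l^2 / sum r;
    GLevNonU = sum_g (sum_l r)^2 / sum r; RLNonUni = sum_l (sum_g r)^2 / sum r;
    Fraction = sum r / pixels traversed.
    """
    runs, traversed = rlm_runs(q, direction)
    if not runs:
        return {f"{direction}_{s}": 0.0 for s in RLM_STATS}
    total = sum(runs.values())
    shrt = sum(r / l**2 for (_, l), r in runs.items()) / total
    lng = sum(r * l**2 for (_, l), r in runs.items()) / total
    by_g: dict[int, int] = {}
    by_l: dict[int, int] = {}
    for (g, l), r in runs.items():
        by_g[g] = by_g.get(g, 0) + r
        by_l[l] = by_l.get(l, 0) + r
    glev = sum(v**2 for v in by_g.values()) / total
    rlnu = sum(v**2 for v in by_l.values()) / total
    frac = total / traversed
    vals = (shrt, lng, glev, rlnu, frac)
    return {f"{direction}_{s}": float(v) for s, v in zip(RLM_STATS, vals)}


# ---------------------------------------------------------------------------
# Absolute gradient (GRA)
# ---------------------------------------------------------------------------


def _interior(mask: np.ndarray) -> np.ndarray:
    """Pixels whose four edge-neighbors are all masked."""
    interior = mask.copy()
    interior[[0, -1], :] = False
    interior[:, [0, -1]] = False
    inner = np.zeros_like(mask)
    inner[1:-1, 1:-1] = (
        mask[1:-1, 1:-1]
        & mask[:-2, 1:-1]
        & mask[2:, 1:-1]
        & mask[1:-1, :-2]
        & mask[1:-1, 2:]
    )
    return inner


def gra_features(q: QuantizedROI) -> dict[str, float]:
    """Absolute-gradient statistics over interior (4-neighborhood) pixels."""
    inner = _interior(q.mask)
    if not inner.any():
        logger.warning("GRA: ROI has no interior pixel; features set to 0")
        return {k: 0.0 for k in GRA_NAMES}
    lv = q.levels.astype(np.float64)
    gx = np.zeros_like(lv)
    gy = np.zeros_like(lv)
    gx[:, 1:-1] = lv[:, 2:] - lv[:, :-2]
    gy[1:-1, :] = lv[2:, :] - lv[:-2, :]
    mag = np.hypot(gx, gy)[inner]
    mean, var, skew, kurt = _moments(mag)
    nonzero = float((mag > 0).mean())
    vals = (mean, var, skew, kurt, nonzero)
    return dict(zip(GRA_NAMES, (float(v) for v in vals)))


# ---------------------------------------------------------------------------
# Autoregressive model (ARM)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ARModelFit:
    """Causal 2-D AR(1) fit: I(s) = sum theta_i * I(neighbor_i) + e(s)."""

    theta: np.ndarray  # (4,) weights for W, NW, N, NE neighbors
    sigma: float  # RMS residual on the fitted pixel set

    def as_features(self) -> dict[str, float]:
        return dict(zip(ARM_NAMES, (*map(float, self.theta), float(self.sigma))))


_MIN_ARM_PIXELS = 20


def arm_features(q: QuantizedROI) -> ARModelFit:
    """Least-squares causal AR model over pixels with masked W/NW/N/NE.

    Levels are centered on the ROI mean before fitting (the AR model
    describes fluctuations around the mean; without centering the weights
    would absorb the mean level itself).  Uses the minimum-norm solution
    when the normal system is singular (e.g. constant ROI).  With fewer
    than 20 eligible pixels the fit is degenerate: theta = 0, sigma = 0,
    with a logged warning.
    """
    lv = q.levels.astype(np.float64)
    lv = lv - float(lv[q.mask].mean()) if q.mask.any() else lv
    mask = q.mask
    h, w = lv.shape
    if h < 2 or w < 3:
        logger.warning("ARM: ROI too small for the causal neighborhood")
        return ARModelFit(theta=np.zeros(4), sigma=0.0)
    c = mask[1:, 1:-1]  # candidate centers (r >= 1, 1 <= col <= w-2)
    west = mask[1:, :-2]
    nw = mask[:-1, :-2]
    north = mask[:-1, 1:-1]
    ne = mask[:-1, 2:]
    elig = c & west & nw & north & ne
    n_elig = int(elig.sum())
    if n_elig < _MIN_ARM_PIXELS:
        logger.warning("ARM: only %d eligible pixels (< %d)", n_elig, _MIN_ARM_PIXELS)
        return ARModelFit(theta=np.zeros(4), sigma=0.0)
    y = lv[1:, 1:-1][elig]
    X = np.column_stack(
        [
            lv[1:, :-2][elig],  # W
            lv[:-1, :-2][elig],  # NW
            lv[:-1, 1:-1][elig],  # N
            lv[:-1, 2:][elig],  # NE
        ]
    )
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    sigma = float(np.sqrt((resid**2).mean()))
    return ARModelFit(theta=theta, sigma=sigma)


# ---------------------------------------------------------------------------
# Haar wavelet energies (WAV)
# ---------------------------------------------------------------------------

_WAV_MAX_SCALE = 5


def _haar_step(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One orthonormal 2-D Haar analysis step on an even-sized block.

    Returns (LL, LH, HL, HH) where HL is high-pass along x (columns) and
    LH high-pass along y (rows); each 2x2 analysis vector has unit norm.
    """
    p = block[0::2, 0::2]
    qq = block[0::2, 1::2]
    r = block[1::2, 0::2]
    s = block[1::2, 1::2]
    ll = (p + qq + r + s) / 2.0
    hl = (-p + qq - r + s) / 2.0
    lh = (-p - qq + r + s) / 2.0
    hh = (p - qq - r + s) / 2.0
    return ll, lh, hl, hh


def wav_features(q: QuantizedROI) -> dict[str, float]:
    """Mean squared Haar coefficients per subband and scale (20 values).

    The mask bounding box is padded with the ROI mean level to the next
    power of two, then transformed by the iterated orthonormal 2-D Haar
    analysis for up to 5 scales.  A coefficient position is counted for a
    subband energy when its spatial support square overlaps at least one
    mask pixel; missing scales (box too small) are emitted as 0.
    """
    mask = q.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub_mask = mask[r0:r1, c0:c1]
    lv = q.levels[r0:r1, c0:c1].astype(np.float64)
    roi_mean = float(q.masked_levels().mean())
    block = np.full(sub_mask.shape, roi_mean)
    block[sub_mask] = lv[sub_mask]

    side = 1 << int(np.ceil(np.log2(max(block.shape + (2,)))))
    padded = np.full((side, side), roi_mean)
    padded[: block.shape[0], : block.shape[1]] = block
    support = np.zeros((side, side), dtype=bool)
    support[: sub_mask.shape[0], : sub_mask.shape[1]] = sub_mask

    out = {f"WavEn{sb}_s-{k}": 0.0 for k in range(1, _WAV_MAX_SCALE + 1) for sb in ("LL", "LH", "HL", "HH")}
    cur = padded
    cur_support = support
    scale = 1
    while scale <= _WAV_MAX_SCALE and cur.shape[0] >= 2:
        ll, lh, hl, hh = _haar_step(cur)
        # a coefficient's support square overlaps the mask iff any of its
        # four child positions did
        sup = (
            cur_support[0::2, 0::2]
            | cur_support[0::2, 1::2]
            | cur_support[1::2, 0::2]
            | cur_support[1::2, 1::2]
        )
        if sup.any():
            for sb, coef in (("LL", ll), ("LH", lh), ("HL", hl), ("HH", hh)):
                out[f"WavEn{sb}_s-{scale}"] = float((coef[sup] ** 2).mean())
        cur, cur_support = ll, sup
        scale += 1
    return out


def texture_features(q: QuantizedROI) -> dict[str, float]:
    """All 279 texture features (HIS + COM + RLM + GRA + ARM + WAV)."""
    out: dict[str, float] = {}
    out.update(his_features(q))
    for offset in COM_OFFSETS:
        m = com_matrix(q, offset)
        if m.degenerate:
            logger.warning("COM: degenerate matrix at offset %s", offset)
        stats = com_features(m)
        for stat, v in stats.items():
            out[com_name(offset[0], offset[1], stat)] = v
    for direction in RLM_DIRECTIONS:
        out.update(rlm_features(q, direction))
    out.update(gra_features(q))
    out.update(arm_features(q).as_features())
    out.update(wav_features(q))
    return out
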