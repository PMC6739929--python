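"""Full-registry feature extraction for one lesion or a whole cohort."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .prep import compute_norm_params, quantize_roi
from .registry import all_names
from .shape import geo_features
from .texture import texture_features

logger = logging.getLogger(__name__)

__all__ = ["extract_all", "extract_cohort"]


def extract_all(image, mask, n_levels: int = 64) -> dict[str, float]:
    """Extract all 352 registry features from one lesion image + mask.

    The image is normalized to mu +/- 3 sigma over the masked pixels and
    quantized to ``n_levels`` gray levels; texture families are computed on
    the quantized ROI and the GEO family on the mask alone.  The result is
    an ordered mapping following the canonical registry; every value is
    finite (family-level degeneracies surface as zeros, not NaN).
    """
    mask = np.asarray(mask).astype(bool)
    params = compute_norm_params(image, mask, n_levels=n_levels)
    q = quantize_roi(image, mask, params)
    values = texture_features(q)
    values.update(geo_features(mask))
    row = {name: float(values[name]) for name in all_names()}
    bad = [k for k, v in row.items() if not np.isfinite(v)]
    if bad:  # defensive: the families themselves guarantee finiteness
        logger.warning("non-finite features zeroed: %s", bad)
        for k in bad:
            row[k] = 0.0
    return row


def extract_cohort(manifest, n_levels: int = 64) -> pd.DataFrame:
    """Feature table (sample_id + 352 columns) for every manifest row."""
    from .io import read_lesion  # local import to avoid a cycle

    rows = []
    for rec in manifest.itertuples(index=False):
        image, mask = read_lesion(rec.image, rec.mask)
        row = {"sample_id": rec.sample_id}
        row.update(extract_all(image, mask, n_levels=n_levels))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *all_names()])
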