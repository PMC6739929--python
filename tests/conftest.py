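import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radiomic.synthetic import ClassRecipe, generate_lesion


@pytest.fixture(scope="session")
def disk_mask():
    yy, xx = np.mgrid[0:64, 0:64]
    return (xx - 32.0) ** 2 + (yy - 32.0) ** 2 <= 20.0**2


@pytest.fixture(scope="session")
def smooth_lesion():
    """One seeded synthetic lesion with moderate texture."""
    recipe = ClassRecipe(
        name="TN",
        correlation_length=2.0,
        contrast_amplitude=80.0,
        noise_sd=10.0,
        elongation=1.2,
        spiculation_amplitude=0.08,
        mean_radius=18.0,
    )
    return generate_lesion(recipe, 96, seed=11)


def random_masked_lesion(rng, size=8, n_levels=6):
    """Small random quantized lesion with a random (nonempty) mask."""
    levels = rng.integers(1, n_levels + 1, size=(size, size))
    mask = rng.random((size, size)) < 0.7
    if not mask.any():
        mask[size // 2, size // 2] = True
    return np.where(mask, levels, 0), mask
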