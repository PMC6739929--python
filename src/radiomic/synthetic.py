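"""Synthetic lesion-image generator with class-controlled texture and shape.

Stands in for patient MRI data: each class recipe controls the interior
texture of the lesion (a Gaussian-smoothed, standardized random field with
a tunable correlation length, scaled by a contrast amplitude, plus white
noise) and the outline shape (an ellipse of given elongation whose
boundary radius is perturbed by low-order sinusoids with seeded random
phases — "spiculation").  Lesions sit on a flat parenchyma-like background
and are written as 16-bit TIFFs with 8-bit PNG masks and a manifest CSV.

Everything is a pure function of (recipe/spec, seed); per-sample seeds are
derived from the cohort seed, the class index, and the sample index, so a
cohort can be extended without reshuffling earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .classify import SUBTYPE_TO_RECEPTORS
from .io import write_lesion, write_manifest

__all__ = ["ClassRecipe", "SyntheticCohortSpec", "generate_lesion", "generate_cohort"]

_SPICULE_ORDERS = np.arange(5, 13)  # low angular orders keep masks simply connected


@dataclass(frozen=True)
class ClassRecipe:
    """Texture/shape recipe of one lesion class.

    correlation_length   smoothness of the interior random field (pixels)
    contrast_amplitude   intensity scale of the texture field
    noise_sd             white-noise SD added inside the lesion
    elongation           major/minor axis ratio of the base ellipse (>= 1)
    spiculation_amplitude  boundary perturbation as a fraction of the mean
                           radius, in [0, 0.5]
    mean_radius          mean lesion radius in pixels (>= 8)
    """

    name: str
    correlation_length: float = 2.0
    contrast_amplitude: float = 80.0
    noise_sd: float = 10.0
    elongation: float = 1.0
    spiculation_amplitude: float = 0.05
    mean_radius: float = 20.0

    def __post_init__(self):
        if not self.name:
            raise ValueError("recipe needs a nonempty name")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.contrast_amplitude < 0:
            raise ValueError("contrast_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if not 0 <= self.spiculation_amplitude <= 0.5:
            raise ValueError("spiculation_amplitude must be in [0, 0.5]")
        if self.mean_radius < 8:
            raise ValueError("mean_radius must be >= 8 pixels")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A full synthetic cohort: recipes, per-class counts, frame, seed."""

    recipes: tuple[ClassRecipe, ...]
    n_per_class: tuple[int, ...]
    image_size: int = 256
    background_level: float = 400.0
    background_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not self.recipes:
            raise ValueError("at least one recipe required")
        names = [r.name for r in self.recipes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate recipe names: {names}")
        if len(self.n_per_class) != len(self.recipes):
            raise ValueError("n_per_class must match recipes")
        if any(n < 2 for n in self.n_per_class):
            raise ValueError("need n_per_class >= 2 for every class")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        recipes = tuple(ClassRecipe(**r) for r in raw.pop("recipes"))
        n_per_class = tuple(int(n) for n in raw.pop("n_per_class"))
        return cls(recipes=recipes, n_per_class=n_per_class, **raw)


def generate_lesion(
    recipe: ClassRecipe,
    image_size: int,
    seed: int,
    background_level: float = 400.0,
    background_noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion image (uint16) and its binary mask.

    The boundary radius is r(phi) = R * (1 + a * sum_m w_m cos(m phi +
    psi_m)) over angular orders 5..12 with seeded random phases and convex
    weights w_m, scaled anisotropically by the elongation (area-preserving:
    sqrt(e) along x, 1/sqrt(e) along y).  Interior intensity is
    background + contrast * standardized Gaussian-smoothed white noise +
    white noise; values are clipped to the 16-bit range.
    """
    if image_size < 4 * recipe.mean_radius:
        raise ValueError(
            f"image_size {image_size} < 4 * mean_radius ({4 * recipe.mean_radius:g})"
        )
    r_extreme = recipe.mean_radius * (1 + recipe.spiculation_amplitude) * np.sqrt(
        recipe.elongation
    )
    if r_extreme >= image_size / 2 - 1:
        raise ValueError(
            f"lesion exceeds frame: maximum radius {r_extreme:.1f} px "
            f"vs half-frame {image_size / 2 - 1:.1f} px"
        )
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=len(_SPICULE_ORDERS))
    w = rng.uniform(0.5, 1.0, size=len(_SPICULE_ORDERS))
    w = w / w.sum()

    center = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dx = (xx - center) / np.sqrt(recipe.elongation)
    dy = (yy - center) * np.sqrt(recipe.elongation)
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    pert = np.zeros_like(phi)
    for order, weight, psi in zip(_SPICULE_ORDERS, w, phases):
        pert += weight * np.cos(order * phi + psi)
    r_phi = recipe.mean_radius * (1.0 + recipe.spiculation_amplitude * pert)
    mask = rho <= r_phi
    # keep the largest 4-connected component (star-shaped outlines are
    # connected; this guards against stray diagonal-only pixels)
    lab, n = ndimage.label(mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)

    field = ndimage.gaussian_filter(
        rng.standard_normal((image_size, image_size)), sigma=recipe.correlation_length
    )
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    noise = rng.standard_normal((image_size, image_size)) * recipe.noise_sd

    image = np.full((image_size, image_size), float(background_level))
    if background_noise_sd > 0:
        image += rng.standard_normal((image_size, image_size)) * background_noise_sd
    interior = background_level + recipe.contrast_amplitude * field + noise
    image[mask] = interior[mask]
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    return image, mask


def sample_seed(cohort_seed: int, class_index: int, sample_index: int) -> int:
    """Deterministic per-sample seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(class_index), int(sample_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(spec: SyntheticCohortSpec, out_dir) -> pd.DataFrame:
    """Write the cohort's images, masks, and manifest CSV; return the manifest.

    Subtype labels come from the recipe names; when a name is one of the
    canonical molecular subtypes the receptor columns are filled through
    the inverse of the IHC surrogate mapping, otherwise they are unknown.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, (recipe, n) in enumerate(zip(spec.recipes, spec.n_per_class)):
        for si in range(n):
            seed = sample_seed(spec.seed, ci, si)
            image, mask = generate_lesion(
                recipe,
                spec.image_size,
                seed,
                background_level=spec.background_level,
                background_noise_sd=spec.background_noise_sd,
            )
            sid = f"{recipe.name}_{si:03d}"
            img_path = out_dir / f"{sid}.tif"
            mask_path = out_dir / f"{sid}_mask.png"
            write_lesion(image, mask, img_path, mask_path)
            er, pr, her2 = SUBTYPE_TO_RECEPTORS.get(
                recipe.name, ("unknown", "unknown", "unknown")
            )
            rows.append(
                {
                    "sample_id": sid,
                    "image": str(img_path),
                    "mask": str(mask_path),
                    "er": er,
                    "pr": pr,
                    "her2": her2,
                    "subtype": recipe.name,
                }
            )
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
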