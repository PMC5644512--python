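"""Seeded generator of synthetic nucleus images.

Emulates Papanicolaou-stained squamous-cell nuclei at the level the
feature set probes: an elliptical nucleus with a noisy bright background
and dark chromatin blobs whose count, size, outline irregularity, radial
spread from the nucleus center and quadrant bias are controllable per
class.  Blob outlines are perturbed with low-order periodic radial noise
(3-8 harmonics) so the convex-hull-ratio complexity of the binarized
chromatin is tunable.

Seven default recipes grade these knobs from normal (NOR: few small
regular central blobs) to carcinoma (SCC: many large irregular spread
blobs with a strong quadrant bias), giving a benchmark with the
qualitative ordering reported for real cervical nuclei.  It is a test
harness, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as _features
from .io import CLASS_LABELS, NucleusImage

__all__ = [
    "NucleusRecipe",
    "generate_nucleus",
    "default_class_recipes",
    "generate_class_dataset",
]


@dataclass(frozen=True)
class NucleusRecipe:
    """Parameters of one synthetic nucleus class.

    ``boundary_irregularity`` is the relative amplitude of the periodic
    radial noise on blob outlines (0 = circular blobs); ``radial_spread``
    places blob centers at that fraction of the local ellipse radius;
    ``quadrant_weights`` biases blob placement over the four
    ellipse-frame quadrants.
    """

    canvas: int = 96
    semi_major: float = 18.0
    semi_minor: float = 14.0
    background_intensity: int = 180
    blob_count: int = 5
    blob_radius_mean: float = 2.6
    blob_radius_sd: float = 0.5
    blob_intensity: int = 90
    boundary_irregularity: float = 0.1
    radial_spread: float = 0.4
    quadrant_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.blob_intensity >= self.background_intensity:
            raise ValueError("chromatin blobs must be darker than the background")
        if max(self.semi_major, self.semi_minor) > self.canvas / 2 - 4:
            raise ValueError("ellipse must fit the canvas with >= 4 px margin")
        w = np.asarray(self.quadrant_weights, dtype=float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("quadrant_weights must be non-negative and sum to 1")


def _blob_outline_radii(
    rng: np.random.Generator, base_radius: float, irregularity: float, angles: np.ndarray
) -> np.ndarray:
    """Radius per angle: base * (1 + irregularity * bounded periodic noise)."""
    if irregularity <= 0:
        return np.full_like(angles, base_radius)
    harmonics = rng.integers(3, 9, size=3)
    amps = rng.random(3)
    amps /= amps.sum()
    phases = rng.uniform(0, 2 * np.pi, size=3)
    noise = sum(a * np.cos(h * angles + p) for a, h, p in zip(amps, harmonics, phases))
    return base_radius * (1.0 + irregularity * noise)


def generate_nucleus(
    recipe: NucleusRecipe,
    seed: int,
    identifier: str = "",
    label: str | None = None,
) -> NucleusImage:
    """Render one synthetic nucleus; bit-identical for a given recipe + seed."""
    rng = np.random.default_rng(seed)
    n = recipe.canvas
    cy = cx = (n - 1) / 2.0
    a, b = recipe.semi_major, recipe.semi_minor
    theta = rng.uniform(0, np.pi)  # ellipse orientation

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # Coordinates in the ellipse frame (u along the major axis).
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    img = np.full((n, n), 255.0)
    noise = rng.normal(0.0, recipe.noise_sd, size=(n, n))
    img[mask] = recipe.background_intensity + noise[mask]

    for _ in range(recipe.blob_count):
        quadrant = int(rng.choice(4, p=np.asarray(recipe.quadrant_weights)))
        # Quadrants of the ellipse frame: (+,+), (+,-), (-,+), (-,-) in (u, v).
        su = 1.0 if quadrant in (0, 1) else -1.0
        sv = 1.0 if quadrant in (0, 2) else -1.0
        phi = rng.uniform(0, np.pi / 2)
        bu = su * np.cos(phi)
        bv = sv * np.sin(phi)
        # Local ellipse radius along (bu, bv) and the blob-center position.
        r_e = 1.0 / np.sqrt((bu / a) ** 2 + (bv / b) ** 2)
        dist = recipe.radial_spread * r_e * rng.uniform(0.75, 1.0)
        cu, cv = bu * dist, bv * dist
        # Back to image coordinates.
        by = cy + cu * np.cos(theta) - cv * np.sin(theta)
        bx = cx + cu * np.sin(theta) + cv * np.cos(theta)

        r0 = max(1.2, rng.normal(recipe.blob_radius_mean, recipe.blob_radius_sd))
        py, px = yy - by, xx - bx
        d = np.hypot(py, px)
        ang = np.arctan2(py, px)
        radii = _blob_outline_radii(rng, r0, recipe.boundary_irregularity, ang)
        blob = (d <= radii) & mask  # blobs clipped to the nuclear mask
        img[blob] = recipe.blob_intensity

    return NucleusImage(
        np.clip(np.rint(img), 0, 255).astype(np.uint8),
        mask,
        identifier=identifier,
        label=label,
    )


def default_class_recipes(canvas: int = 96) -> dict[str, NucleusRecipe]:
    """The seven default class recipes, graded from NOR to SCC."""
    base = dict(canvas=canvas, background_intensity=180, noise_sd=3.0)
    return {
        "NOR": NucleusRecipe(semi_major=14, semi_minor=11, blob_count=3,
                             blob_radius_mean=2.2, blob_radius_sd=0.4,
                             blob_intensity=100, boundary_irregularity=0.05,
                             radial_spread=0.30, **base),
        "MET": NucleusRecipe(semi_major=13, semi_minor=12, blob_count=5,
                             blob_radius_mean=2.0, blob_radius_sd=0.4,
                             blob_intensity=110, boundary_irregularity=0.05,
                             radial_spread=0.35, **base),
        "REG": NucleusRecipe(semi_major=23, semi_minor=17, blob_count=5,
                             blob_radius_mean=2.6, blob_radius_sd=0.5,
                             blob_intensity=100, boundary_irregularity=0.10,
                             radial_spread=0.40, **base),
        "LSIL": NucleusRecipe(semi_major=17, semi_minor=13, blob_count=7,
                              blob_radius_mean=2.6, blob_radius_sd=0.5,
                              blob_intensity=90, boundary_irregularity=0.20,
                              radial_spread=0.55,
                              quadrant_weights=(0.32, 0.26, 0.22, 0.20), **base),
        "HSIL": NucleusRecipe(semi_major=16, semi_minor=11, blob_count=9,
                              blob_radius_mean=2.9, blob_radius_sd=0.5,
                              blob_intensity=85, boundary_irregularity=0.32,
                              radial_spread=0.62,
                              quadrant_weights=(0.38, 0.24, 0.20, 0.18), **base),
        "CIS": NucleusRecipe(semi_major=19, semi_minor=13, blob_count=11,
                             blob_radius_mean=3.1, blob_radius_sd=0.5,
                             blob_intensity=78, boundary_irregularity=0.42,
                             radial_spread=0.72,
                             quadrant_weights=(0.45, 0.22, 0.18, 0.15), **base),
        "SCC": NucleusRecipe(semi_major=21, semi_minor=13, blob_count=13,
                             blob_radius_mean=3.3, blob_radius_sd=0.5,
                             blob_intensity=70, boundary_irregularity=0.55,
                             radial_spread=0.80,
                             quadrant_weights=(0.52, 0.20, 0.15, 0.13), **base),
    }


def generate_class_dataset(
    recipes: dict[str, NucleusRecipe] | None = None,
    n_per_class: int = 20,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[NucleusImage], pd.DataFrame]:
    """Generate nuclei per class and extract the labeled 46-feature table.

    Per-nucleus seeds derive from the master seed; nucleus size and blob
    count jitter mildly around the recipe values.  When ``out_dir`` is
    given, image/mask PNG pairs are written there.
    """
    recipes = recipes if recipes is not None else default_class_recipes()
    rng = np.random.default_rng(seed)
    nuclei: list[NucleusImage] = []
    for label in sorted(recipes, key=_class_key):
        recipe = recipes[label]
        for i in range(n_per_class):
            scale = rng.uniform(0.85, 1.15)
            jitter = int(rng.integers(-1, 2))
            variant = replace(
                recipe,
                semi_major=recipe.semi_major * scale,
                semi_minor=recipe.semi_minor * scale,
                blob_count=max(0, recipe.blob_count + jitter),
            )
            nuc_seed = int(rng.integers(2**31))
            nuclei.append(
                generate_nucleus(
                    variant, nuc_seed, identifier=f"{label}_{i:03d}", label=label
                )
            )
    table = _features.extract_table(nuclei)
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for nuc in nuclei:
            iio.imwrite(out / f"{nuc.identifier}.png", nuc.intensities)
            iio.imwrite(
                out / f"{nuc.identifier}_mask.png",
                (nuc.mask * 255).astype(np.uint8),
            )
    return nuclei, table


def _class_key(label: str):
    try:
        return (0, CLASS_LABELS.index(label))
    except ValueError:
        return (1, label)
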