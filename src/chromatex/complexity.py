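"""Chromatin-complexity features from a binarization-threshold sweep.

For every threshold i in 0..255 the masked image is binarized with dark
pixels (intensity <= i) as foreground — chromatin stains dark, so
complexity is measured on dark regions.  Per threshold the sweep stores

* ``L(i)``  — summed marching-squares perimeter of all foreground
  contours, hole boundaries included;
* ``LC(i)`` — convex-hull perimeter of the joint foreground contour
  points (one hull for the whole foreground);
* ``Lr(i) = L(i) / (LC(i) * f10)`` — hull ratio normalized by the
  nucleus's own outline hull ratio f10, so a wrinkled nuclear outline is
  not double counted;
* ``D(i)``  — box-counting dimension of the foreground boundary pixels.

Thresholds with empty foreground are left undefined (NaN) and skipped by
all downstream sums, so degenerate early thresholds do not dilute them.

Features
--------
f34 contour complexity   sum over {i : L(i) > f2} of (L(i)/f2 - 1)
f35 fractal feature      max over i of D(i)
f40 hull-ratio fill area sum over {i : Lr(i) >= 1} of (Lr(i) - 1)
f41, f42, f43            number of thresholds with Lr(i) >= 1.1, 1.2, 1.3
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import NucleusImage
from .morphometry import (
    convex_hull_of_points,
    mask_contours,
    polygon_length,
    region_geometry,
    shape_features,
)

__all__ = [
    "ThresholdSweep",
    "binarize_at",
    "threshold_sweep",
    "box_counting_dimension",
    "contour_complexity",
    "fractal_feature",
    "convex_complexity_features",
]

BOX_SIZES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64)

_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class ThresholdSweep:
    """Per-threshold quantities of the binarization sweep (NaN = undefined)."""

    thresholds: np.ndarray       # 0..255
    L: np.ndarray                # contour perimeter
    LC: np.ndarray               # convex hull perimeter
    Lr: np.ndarray               # L / (LC * f10)
    D: np.ndarray                # box-counting dimension
    foreground_count: np.ndarray # pixels
    f10: float


def binarize_at(nucleus: NucleusImage, i: int) -> np.ndarray:
    """Foreground = masked pixels with intensity <= i (dark chromatin)."""
    if not 0 <= i <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return nucleus.mask & (nucleus.intensities <= i)


def box_counting_dimension(
    binary: np.ndarray, sizes: tuple[int, ...] = BOX_SIZES
) -> float:
    """Box-counting dimension of the True pixels of a binary grid.

    The box grid is anchored at the point set's bounding-box corner, and
    sizes larger than a quarter of the set's extent are dropped (keeping
    at least the three smallest): boxes much larger than the object count
    a constant handful of cells and would flatten the slope.  Returns the
    least-squares slope of log(count) versus log(1/size).
    """
    coords = np.argwhere(binary)
    if coords.size == 0:
        raise ValueError("empty point set")
    coords = coords - coords.min(axis=0)
    extent = max(int(coords.max()) + 1, 1)
    used = [s for s in sizes if s <= max(extent / 4.0, sizes[min(2, len(sizes) - 1)])]
    counts = []
    for s in used:
        boxes = coords // s
        counts.append(len(np.unique(boxes, axis=0)))
    logc = np.log(np.asarray(counts, dtype=np.float64))
    x = np.log(1.0 / np.asarray(used, dtype=np.float64))
    slope = np.polyfit(x, logc, 1)[0]
    return float(slope)


def _boundary_pixels(fg: np.ndarray) -> np.ndarray:
    return fg & ~ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)


def threshold_sweep(nucleus: NucleusImage, f10: float | None = None) -> ThresholdSweep:
    """Run the full 256-threshold binarization sweep.

    The foreground only changes at intensity values actually present in
    the masked region, so geometry is computed once per distinct
    foreground and replicated across the constant threshold ranges.
    """
    if f10 is None:
        f10 = shape_features(region_geometry(nucleus))["f10"]

    n = 256
    L = np.full(n, np.nan)
    LC = np.full(n, np.nan)
    D = np.full(n, np.nan)
    count = np.zeros(n, dtype=np.int64)

    vals = np.unique(nucleus.masked_values)
    hist = np.bincount(nucleus.masked_values, minlength=256)
    cum = np.cumsum(hist)

    for k, v in enumerate(vals):
        fg = binarize_at(nucleus, int(v))
        contours = mask_contours(fg)
        l_val = sum(polygon_length(c) for c in contours)
        pts = np.vstack(contours)
        _, lc_val, _ = convex_hull_of_points(pts)
        d_val = box_counting_dimension(_boundary_pixels(fg))
        hi = int(vals[k + 1]) if k + 1 < len(vals) else 256
        L[v:hi] = l_val
        LC[v:hi] = lc_val
        D[v:hi] = d_val
    count[:] = cum

    with np.errstate(invalid="ignore", divide="ignore"):
        Lr = L / (LC * f10)
    return ThresholdSweep(
        thresholds=np.arange(n),
        L=L,
        LC=LC,
        Lr=Lr,
        D=D,
        foreground_count=count,
        f10=float(f10),
    )


def contour_complexity(sweep: ThresholdSweep, f2: float) -> float:
    """f34: excess contour perimeter summed over thresholds with L(i) > f2."""
    L = sweep.L
    mask = np.isfinite(L) & (L > f2)
    if not mask.any():
        return 0.0
    return float((L[mask] / f2 - 1.0).sum())


def fractal_feature(sweep: ThresholdSweep) -> float:
    """f35: maximum box-counting dimension over the sweep."""
    d = sweep.D[np.isfinite(sweep.D)]
    if d.size == 0:
        warnings.warn("no defined fractal dimension in sweep; f35 set to 0")
        return 0.0
    return float(d.max())


def convex_complexity_features(sweep: ThresholdSweep) -> dict[str, float]:
    """f40-f43 from the normalized hull-ratio curve Lr(i)."""
    lr = sweep.Lr[np.isfinite(sweep.Lr)]
    return {
        "f40": float((lr[lr >= 1.0] - 1.0).sum()),
        "f41": int((lr >= 1.1).sum()),
        "f42": int((lr >= 1.2).sum()),
        "f43": int((lr >= 1.3).sum()),
    }
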