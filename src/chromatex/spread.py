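"""Chromatin-distribution spreading: chromatin image, gravity center, f44.

The masked intensity histogram is split by the between-class-variance
maximizing threshold (Otsu's discriminant criterion) to separate
dark-stained chromatin from lighter non-chromatin.  The chromatin image
inverts intensities and subtracts the threshold as a bias,

    I'(Z) = 255 - I(Z) - Th   if I(Z) + Th < 255, else 0,

so densely stained pixels get high values.  f44 is the normalized second
moment of I' about its intensity-weighted centroid G:

    f44 = (1/f1) * sum_Z (|G - Z| / f3)^2 * I'(Z),

with f1 the nuclear area and f3 the longest diameter.  Large values mean
chromatin mass spread far from its gravity center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import NucleusImage

__all__ = [
    "ChromatinImage",
    "discriminant_threshold",
    "chromatin_image",
    "gravity_center",
    "cds_value",
]


@dataclass
class ChromatinImage:
    """Inverted, bias-subtracted chromatin intensity grid I'."""

    iprime: np.ndarray   # float grid, 0 outside the mask
    Th: int
    mask: np.ndarray
    total_mass: float


def discriminant_threshold(values: np.ndarray) -> int:
    """Otsu threshold of the 256-bin histogram (ties toward the smaller value).

    Scans all 256 candidate thresholds t and maximizes the between-class
    variance w0 * w1 * (mu0 - mu1)^2 of the split {<= t} / {> t}.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise ValueError("empty intensity sample")
    hist = np.bincount(v.astype(np.intp), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) == 1:
        th = int(np.flatnonzero(hist)[0])
        warnings.warn(f"constant intensity sample; threshold set to {th}")
        return th
    total = hist.sum()
    w0 = np.cumsum(hist) / total                      # weight of class {<= t}
    mu_cum = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mu_total * w0 - mu_cum) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -np.inf
    return int(np.argmax(between))  # argmax takes the first (smallest) maximizer


def chromatin_image(nucleus: NucleusImage, Th: int | None = None) -> ChromatinImage:
    """Build the chromatin image I' inside the mask (zeros outside)."""
    if Th is None:
        Th = discriminant_threshold(nucleus.masked_values)
    if not 0 <= Th <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    I = nucleus.intensities.astype(np.float64)
    iprime = np.where(nucleus.mask & (I + Th < 255), 255.0 - I - Th, 0.0)
    return ChromatinImage(iprime, int(Th), nucleus.mask, float(iprime.sum()))


def gravity_center(chromatin: ChromatinImage) -> np.ndarray:
    """Intensity-weighted centroid of I' as float (row, col) coordinates.

    Falls back to the mask centroid (with a warning) when I' carries no
    mass; f44 is then 0 by construction.
    """
    if chromatin.total_mass <= 0:
        warnings.warn("chromatin image has zero mass; using mask centroid")
        return np.argwhere(chromatin.mask).mean(axis=0)
    coords = np.argwhere(chromatin.iprime > 0).astype(np.float64)
    w = chromatin.iprime[chromatin.iprime > 0]
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def cds_value(
    chromatin: ChromatinImage, G: np.ndarray, f1: float, f3: float
) -> float:
    """Chromatin-distribution spreading value f44."""
    if f1 <= 0 or f3 <= 0:
        raise ValueError("f1 and f3 must be positive")
    if chromatin.total_mass <= 0:
        return 0.0
    coords = np.argwhere(chromatin.iprime > 0).astype(np.float64)
    w = chromatin.iprime[chromatin.iprime > 0]
    d2 = ((coords - np.asarray(G, dtype=np.float64)) ** 2).sum(axis=1)
    return float((d2 / f3**2 * w).sum() / f1)
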