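"""Intensity-distribution features f11-f18 inside the nuclear mask.

f11 mean intensity
f12 number of pixels attaining the sample maximum
f13 number of pixels attaining the sample minimum
f14 radial distribution: mean center intensity minus mean periphery intensity
f15 skewness (population-moment g1 form)
f16 excess kurtosis (m4/m2^2 - 3)
f17 coefficient of variation (sample SD, n-1 denominator, over mean)
f18 fraction of pixels in the top 20% of the observed intensity range

Degenerate conventions: a constant sample has f15 = f16 = f17 = 0 and
f18 = 1; a zero mean gives f17 = 0.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .io import NucleusImage

__all__ = ["basic_intensity_features", "radial_distribution"]


def basic_intensity_features(values: np.ndarray) -> dict[str, float]:
    """Features f11-f13, f15-f18 from the masked intensity sample."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty intensity sample")
    vmin, vmax = float(v.min()), float(v.max())
    out = {
        "f11": float(v.mean()),
        "f12": int((v == vmax).sum()),
        "f13": int((v == vmin).sum()),
    }
    if vmin == vmax:
        warnings.warn("constant intensity sample; moment features set by convention")
        out.update({"f15": 0.0, "f16": 0.0, "f17": 0.0, "f18": 1.0})
        return out
    out["f15"] = float(stats.skew(v, bias=True))
    out["f16"] = float(stats.kurtosis(v, fisher=True, bias=True))
    mean = out["f11"]
    out["f17"] = float(v.std(ddof=1) / mean) if mean != 0 else 0.0
    cutoff = vmin + 0.8 * (vmax - vmin)
    out["f18"] = float((v >= cutoff).mean())
    return out


def radial_distribution(nucleus: NucleusImage) -> float:
    """Radial distribution value f14.

    Center pixels are masked pixels within 0.5 * r_eq of the mask centroid,
    with r_eq = sqrt(area / pi); periphery is the rest.  f14 is the mean
    center intensity minus the mean periphery intensity, so a darker center
    gives a negative value.
    """
    coords = nucleus.masked_coords.astype(np.float64)
    vals = nucleus.masked_values.astype(np.float64)
    centroid = coords.mean(axis=0)
    r_eq = np.sqrt(len(coords) / np.pi)
    dist = np.linalg.norm(coords - centroid, axis=1)
    center = dist <= 0.5 * r_eq
    if not center.any() or center.all():
        warnings.warn("empty center or periphery ring; f14 set to 0")
        return 0.0
    return float(vals[center].mean() - vals[~center].mean())
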