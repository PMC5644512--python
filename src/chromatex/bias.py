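"""Tangential bias of the chromatin distribution (gt, f45, f46).

The nuclear mask is fitted to an ellipse from its second-order moments,
the image is rigidly transformed so the ellipse center lands on the
canvas center with the major axis vertical, and the nucleus is cut into
four quadrants at the axes.  A chromatin feature ft computed on each
quadrant gives four values whose coefficient of variation

    gt = | SD(ft,1..ft,4) / mean(ft,1..ft,4) |     (sample SD, n-1)

measures the tangential bias of that feature.  The two summary features
average intensity-related and run-length-related biases:

    f45 = (g11 + g18 + g24 + g36) / 4
    f46 = (g29 + g30 + g31 + g32) / 4
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import DegenerateInputError, NucleusImage

__all__ = [
    "EllipseFrame",
    "fit_ellipse",
    "align_to_ellipse",
    "split_quadrants",
    "quadrant_bias",
    "tangential_bias_values",
    "QUADRANT_FEATURE_RANGE",
    "INTENSITY_BIAS_FEATURES",
    "TEXTURE_BIAS_FEATURES",
]

#: Feature indices t for which a quadrant bias gt is defined.
QUADRANT_FEATURE_RANGE: tuple[int, ...] = (11, 12, *range(18, 45))

#: The four intensity-related biases averaged into f45.
INTENSITY_BIAS_FEATURES: tuple[int, ...] = (11, 18, 24, 36)

#: The four run-length biases averaged into f46.
TEXTURE_BIAS_FEATURES: tuple[int, ...] = (29, 30, 31, 32)

#: Minimum quadrant size (pixels) for a feature to be considered defined.
MIN_QUADRANT_PIXELS = 8


@dataclass
class EllipseFrame:
    """Moment-fitted ellipse of a nuclear mask."""

    center: tuple[float, float]  # (row, col)
    major_axis: float            # full length, 4*sqrt(largest eigenvalue)
    minor_axis: float
    orientation: float           # radians between the row axis and the major axis


def fit_ellipse(mask: np.ndarray) -> EllipseFrame:
    """Fit an ellipse to the mask from its second central moments."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if minor <= 0:
        raise DegenerateInputError("degenerate (collinear) mask")
    return EllipseFrame(
        center=tuple(float(c) for c in props.centroid),
        major_axis=major,
        minor_axis=minor,
        orientation=float(props.orientation),
    )


def _major_axis_vector(mask: np.ndarray) -> np.ndarray:
    """Unit (row, col) eigenvector of the coordinate covariance, major axis."""
    coords = np.argwhere(mask).astype(np.float64)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    if v[0] < 0:  # canonical sign: major axis points toward increasing rows
        v = -v
    return v


def align_to_ellipse(nucleus: NucleusImage, frame: EllipseFrame) -> NucleusImage:
    """Rotate/translate the nucleus so the ellipse is centered and axis-aligned.

    The major axis maps to the output row (vertical) direction and the
    ellipse center to the canvas center.  Intensities are resampled
    bilinearly, the mask nearest-neighbor.  The canvas is even-sized so
    its center — and hence the quadrant cutting axes — falls between
    pixels: the quadrants always partition the mask exactly, and a
    mirror-symmetric nucleus splits into exactly mirrored quadrants.
    """
    h, w = nucleus.mask.shape
    diag = int(np.ceil(np.hypot(h, w))) + 4
    n = diag + diag % 2  # even canvas
    center_out = np.array([(n - 1) / 2.0, (n - 1) / 2.0])

    v = _major_axis_vector(nucleus.mask)
    p = np.array([-v[1], v[0]])
    R = np.column_stack([v, p])  # output row axis -> major axis direction
    offset = np.asarray(frame.center) - R @ center_out

    intens = ndimage.affine_transform(
        nucleus.intensities.astype(np.float64), R, offset=offset,
        output_shape=(n, n), order=1, mode="constant", cval=255.0,
    )
    mask = ndimage.affine_transform(
        nucleus.mask.astype(np.uint8), R, offset=offset,
        output_shape=(n, n), order=0, mode="constant", cval=0,
    ).astype(bool)
    if not mask.any():
        raise DegenerateInputError("aligned mask is empty")
    return NucleusImage(
        np.clip(np.rint(intens), 0, 255).astype(np.uint8),
        mask,
        identifier=nucleus.identifier,
        label=nucleus.label,
    )


def split_quadrants(aligned: NucleusImage) -> list[NucleusImage]:
    """Cut the aligned nucleus into four quadrants at the canvas axes.

    The quadrant masks partition the nuclear mask; pixels lying exactly
    on a cutting axis would go to the positive side, but the even canvas
    of :func:`align_to_ellipse` places the axes between pixels so the
    case never arises there.  Quadrants are returned cropped to their
    bounding boxes, ordered (+,+), (+,-), (-,+), (-,-) in (row, col)
    sign; empty quadrants are returned as None with a warning.
    """
    h, w = aligned.mask.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rows = np.arange(h)[:, None] >= cr
    cols = np.arange(w)[None, :] >= cc
    half_planes = [
        rows & cols,
        rows & ~cols,
        ~rows & cols,
        ~rows & ~cols,
    ]
    out: list[NucleusImage | None] = []
    for k, hp in enumerate(half_planes):
        qmask = aligned.mask & hp
        if not qmask.any():
            warnings.warn(f"quadrant {k} is empty")
            out.append(None)
            continue
        rr, cc_ = np.nonzero(qmask)
        sl = (slice(rr.min(), rr.max() + 1), slice(cc_.min(), cc_.max() + 1))
        out.append(
            NucleusImage(
                aligned.intensities[sl],
                qmask[sl],
                identifier=f"{aligned.identifier}/q{k}",
                label=aligned.label,
            )
        )
    return out


def _quadrant_values(quadrants, t: int) -> list[float]:
    from . import features  # deferred: features composes this module in turn

    vals = []
    for q in quadrants:
        if q is None or q.area < MIN_QUADRANT_PIXELS:
            vals.append(None)
            continue
        vals.append(features.extract_features(q, names=[f"f{t}"])[f"f{t}"])
    return vals


def _cv_of(values: list[float]) -> float:
    present = [v for v in values if v is not None]
    if len(values) - len(present) >= 2:
        raise DegenerateInputError("feature undefined on two or more quadrants")
    if len(present) < len(values):
        warnings.warn("feature undefined on one quadrant; bias uses the rest")
    arr = np.asarray(present, dtype=np.float64)
    mean = arr.mean()
    if mean == 0:
        warnings.warn("zero mean across quadrants; gt set to 0")
        return 0.0
    return float(abs(arr.std(ddof=1) / mean))


def quadrant_bias(quadrants: list[NucleusImage], t: int) -> float:
    """gt: coefficient of variation of feature ft over the four quadrants."""
    if t not in QUADRANT_FEATURE_RANGE:
        raise ValueError(f"quadrant bias is defined for t in {{11, 12, 18..44}}, got {t}")
    return _cv_of(_quadrant_values(quadrants, t))


def tangential_bias_values(quadrants: list[NucleusImage]) -> tuple[float, float]:
    """(f45, f46): mean intensity-related and run-length-related biases.

    Computes the eight required quadrant features in one extraction pass
    per quadrant so the co-occurrence and run-length matrices are shared.
    """
    from . import features

    needed = sorted(set(INTENSITY_BIAS_FEATURES) | set(TEXTURE_BIAS_FEATURES))
    names = [f"f{t}" for t in needed]
    per_quadrant: list[dict | None] = []
    for q in quadrants:
        if q is None or q.area < MIN_QUADRANT_PIXELS:
            per_quadrant.append(None)
        else:
            per_quadrant.append(features.extract_features(q, names=names))

    def g(t: int) -> float:
        return _cv_of(
            [d[f"f{t}"] if d is not None else None for d in per_quadrant]
        )

    f45 = float(np.mean([g(t) for t in INTENSITY_BIAS_FEATURES]))
    f46 = float(np.mean([g(t) for t in TEXTURE_BIAS_FEATURES]))
    return f45, f46
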