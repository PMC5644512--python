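"""Reading and writing nucleus images, masks, and feature tables.

A *nucleus image* is an 8-bit grayscale intensity grid together with a
same-shape boolean mask that marks the nuclear region.  Color input is
converted to grayscale using the Y (luma) channel of the YCbCr color
system with ITU-R BT.601 weights, the classic definition for 8-bit
imagery.

Feature tables are plain CSV files with one row per nucleus, columns
named ``f1`` .. ``f46`` plus optional ``id`` and ``label`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DegenerateInputError",
    "NucleusImage",
    "FEATURE_NAMES",
    "CLASS_LABELS",
    "rgb_to_gray",
    "load_nucleus",
    "read_feature_table",
    "write_feature_table",
]

#: Canonical names of the 46 per-nucleus features.
FEATURE_NAMES: tuple[str, ...] = tuple(f"f{i}" for i in range(1, 47))

#: The seven-class cytology vocabulary, ordered from negative to malignant.
CLASS_LABELS: tuple[str, ...] = ("NOR", "MET", "REG", "LSIL", "HSIL", "CIS", "SCC")

#: Minimum nuclear-region size accepted when loading (degenerate-region guard).
MIN_REGION_PIXELS = 16

# BT.601 luma weights for R, G, B.
_BT601 = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised for malformed input files or arrays."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but degenerate (e.g. empty mask)."""


@dataclass
class NucleusImage:
    """8-bit intensity grid plus boolean nuclear mask.

    Parameters
    ----------
    intensities : ndarray of uint8, shape (H, W)
        Grayscale pixel intensities.
    mask : ndarray of bool, shape (H, W)
        True inside the nuclear region.
    identifier : str
        Free-form name, used in feature tables.
    label : str or None
        Optional class label (one of :data:`CLASS_LABELS` for cytology data).

    Pixel coordinates are 0-based ``(row, column)`` throughout the package.
    """

    intensities: np.ndarray
    mask: np.ndarray
    identifier: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 2:
            raise FormatError("intensities must be a 2-D grid")
        if self.intensities.shape != self.mask.shape:
            raise FormatError(
                f"intensity shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        if self.intensities.dtype != np.uint8:
            arr = self.intensities
            if np.any(arr < 0) or np.any(arr > 255):
                raise FormatError("intensity values must lie in [0, 255]")
            self.intensities = arr.astype(np.uint8)
        if not self.mask.any():
            raise DegenerateInputError("mask is empty")

    @property
    def masked_values(self) -> np.ndarray:
        """Intensities of masked pixels in row-major scan order."""
        return self.intensities[self.mask]

    @property
    def masked_coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) coordinates of masked pixels, row-major order."""
        return np.argwhere(self.mask)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def rgb_to_gray(rgb_image: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit image to grayscale via the BT.601 Y value.

    Y = 0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer and
    clipped to [0, 255].
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise FormatError(f"expected a (H, W, 3) RGB image, got shape {rgb.shape}")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise FormatError("RGB values must lie in [0, 255]")
    y = rgb.astype(np.float64) @ _BT601
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def _read_mask(arr: np.ndarray) -> np.ndarray:
    # Accept 0/1, 0/255 or boolean encodings; any nonzero pixel is "inside".
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) != 0


def load_nucleus(
    image_path: str | Path,
    mask_path: str | Path,
    identifier: str | None = None,
    label: str | None = None,
) -> NucleusImage:
    """Load an image/mask pair (PNG or TIFF) into a :class:`NucleusImage`.

    RGB images are converted with :func:`rgb_to_gray`.  The mask may be
    encoded 0/1 or 0/255; any nonzero pixel counts as inside the nucleus.
    """
    img = np.asarray(iio.imread(image_path))
    if img.ndim == 3:
        img = rgb_to_gray(img[..., :3]) if img.shape[-1] in (3, 4) else None
        if img is None:
            raise FormatError(f"unsupported channel count in {image_path}")
    elif img.ndim != 2:
        raise FormatError(f"unsupported image dimensionality in {image_path}")

    mask = _read_mask(np.asarray(iio.imread(mask_path)))
    if mask.shape != img.shape:
        raise FormatError(
            f"image shape {img.shape} does not match mask shape {mask.shape}"
        )
    n_true = int(mask.sum())
    if n_true == 0:
        raise DegenerateInputError(f"mask {mask_path} is empty")
    if n_true < MIN_REGION_PIXELS:
        raise DegenerateInputError(
            f"mask {mask_path} has only {n_true} pixels (< {MIN_REGION_PIXELS})"
        )
    ident = identifier if identifier is not None else Path(image_path).stem
    return NucleusImage(img, mask, identifier=ident, label=label)


_META_COLUMNS = ("id", "label")


def _check_columns(columns) -> None:
    allowed = set(FEATURE_NAMES) | set(_META_COLUMNS)
    unknown = [c for c in columns if c not in allowed]
    if unknown:
        raise FormatError(f"unknown feature-table column(s): {unknown}")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV (12 significant digits per value)."""
    _check_columns(table.columns)
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path)
    _check_columns(table.columns)
    for col in table.columns:
        if col in _META_COLUMNS:
            table[col] = table[col].astype(object)
    if table[[c for c in table.columns if c in FEATURE_NAMES]].isna().any().any():
        raise FormatError(f"missing feature values in {path}")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table, in f1..f46 order."""
    return [c for c in FEATURE_NAMES if c in table.columns]
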