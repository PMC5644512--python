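"""Gray-level co-occurrence and run-length texture features.

Co-occurrence matrices are built at 256 gray levels for the 16
displacement combinations r in {1, 2, 4, 8} pixels and theta in
{0, 45, 90, 135} degrees; pixel pairs are counted only when both pixels
lie inside the nuclear mask, the matrix is symmetrized and normalized to
probabilities.  Fourteen Haralick features (f19-f28, f36-f39) are
computed per matrix and averaged over the 16 matrices.

Run-length matrices are built for the 16 combinations of theta in
{0, 45, 90, 135} degrees and quantization levels {256, 16, 4, 2}
(quantized as floor(I * levels / 256)); a run is a maximal constant-level
segment along a scan line and never crosses an unmasked pixel.  The five
Galloway features (f29-f33) are averaged over the 16 matrices.

All logarithms are natural; 0 * log 0 = 0.  Two of the information
measures deliberately differ from Haralick's classical definitions:
f38 omits the square root of the classical IMC2 and f39 is the
second-largest eigenvalue of Q itself (no square root).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import DegenerateInputError, NucleusImage

__all__ = [
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "GLCM_DISTANCES",
    "ANGLES",
    "RLM_LEVELS",
    "build_glcm",
    "build_glcm_set",
    "haralick_features",
    "build_rlm",
    "build_rlm_set",
    "runlength_features",
]

GLCM_DISTANCES: tuple[int, ...] = (1, 2, 4, 8)
ANGLES: tuple[int, ...] = (0, 45, 90, 135)
RLM_LEVELS: tuple[int, ...] = (256, 16, 4, 2)

# (row, col) unit offsets per angle; 45 degrees points up-right in image coords.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_HARALICK_NAMES = (
    "f19", "f20", "f21", "f22", "f23", "f24", "f25", "f26", "f27", "f28",
    "f36", "f37", "f38", "f39",
)
_RUNLENGTH_NAMES = ("f29", "f30", "f31", "f32", "f33")


@dataclass
class CooccurrenceMatrix:
    """Symmetric, normalized 256x256 co-occurrence probability matrix."""

    P: np.ndarray
    displacement: tuple[int, int]  # (r pixels, theta degrees)
    pair_count: int


@dataclass
class RunLengthMatrix:
    """Run counts R[level, length-1] for one direction and quantization."""

    R: np.ndarray
    theta: int
    levels: int
    total_runs: int


def build_glcm(nucleus: NucleusImage, r: int, theta: int) -> CooccurrenceMatrix:
    """Co-occurrence matrix for displacement (r, theta) within the mask."""
    if r < 1:
        raise ValueError("displacement distance must be >= 1")
    if theta not in _ANGLE_OFFSETS:
        raise ValueError(f"theta must be one of {ANGLES}")
    dr, dc = (o * r for o in _ANGLE_OFFSETS[theta])
    img = nucleus.intensities.astype(np.intp)
    mask = nucleus.mask
    h, w = mask.shape

    # Window of source pixels whose displaced partner stays on the grid.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    counts = np.zeros((256, 256), dtype=np.int64)
    if r0 < r1 and c0 < c1:
        src_m = mask[r0:r1, c0:c1]
        dst_m = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = src_m & dst_m
        i = img[r0:r1, c0:c1][valid]
        j = img[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        np.add.at(counts, (i, j), 1)
    sym = counts + counts.T
    total = int(sym.sum())
    if total == 0:
        warnings.warn(f"no valid pixel pairs for displacement ({r}, {theta})")
        return CooccurrenceMatrix(np.zeros((256, 256)), (r, theta), 0)
    return CooccurrenceMatrix(sym / total, (r, theta), total)


def build_glcm_set(nucleus: NucleusImage) -> list[CooccurrenceMatrix]:
    """The 16 co-occurrence matrices (4 distances x 4 angles)."""
    return [build_glcm(nucleus, r, t) for r in GLCM_DISTANCES for t in ANGLES]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _haralick_single(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    idx = np.arange(n, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    i = idx[:, None]
    j = idx[None, :]

    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    var_x = float(((idx - mu_x) ** 2) @ px)
    var_y = float(((idx - mu_y) ** 2) @ py)

    contrast = float((((i - j) ** 2) * P).sum())
    energy = float((P**2).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        correlation = 0.0  # constant image: correlation undefined, 0 by convention
    variance = var_x
    entropy = _entropy(P)

    # Sum (i+j) and difference |i-j| distributions.
    ii, jj = np.nonzero(P)
    w = P[ii, jj]
    p_sum = np.bincount(ii + jj, weights=w, minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(ii - jj), weights=w, minlength=n)

    k_sum = np.arange(p_sum.size, dtype=np.float64)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)

    k_diff = np.arange(p_diff.size, dtype=np.float64)
    mu_d = float(k_diff @ p_diff)
    diff_variance = float(((k_diff - mu_d) ** 2) @ p_diff)
    diff_entropy = _entropy(p_diff)

    idm = float((P / (1.0 + (i - j) ** 2)).sum())

    # Information measures, as printed: f37 = MI - max(HX, HY);
    # f38 = 1 - exp(-2 (HXY2 - HXY)) with no square root.
    hx = _entropy(px)
    hy = _entropy(py)
    hxy = entropy
    outer = px[ii] * py[jj]
    mi = float((w * np.log(w / outer)).sum())
    f37 = mi - max(hx, hy)

    nz = np.outer(px, py)
    hxy2 = _entropy(nz.ravel())
    f38 = 1.0 - np.exp(-2.0 * (hxy2 - hxy))

    f39 = _maximal_correlation(P, px, py)

    return {
        "f19": contrast,
        "f20": energy,
        "f21": correlation,
        "f22": variance,
        "f23": entropy,
        "f24": sum_variance,
        "f25": sum_entropy,
        "f26": diff_variance,
        "f27": diff_entropy,
        "f28": idm,
        "f36": sum_average,
        "f37": f37,
        "f38": float(f38),
        "f39": f39,
    }


def _maximal_correlation(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Second-largest eigenvalue of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)).

    Rows/columns with empty marginals contribute zero eigenvalues, so the
    computation is restricted to the support of the marginals.
    """
    sup_x = px > 0
    sup_y = py > 0
    A = P[np.ix_(sup_x, sup_y)] / px[sup_x, None]   # P(i,k)/px(i)
    B = P[np.ix_(sup_x, sup_y)] / py[None, sup_y]   # P(j,k)/py(k)
    if A.shape[0] < 2:
        return 0.0
    Q = A @ B.T
    eigs = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
    return float(eigs[1])


def haralick_features(matrices: list[CooccurrenceMatrix]) -> dict[str, float]:
    """Mean of the 14 Haralick features over the matrices with pixel pairs.

    Matrices whose displacement found no valid pairs (mask smaller than the
    displacement) are dropped from the average rather than zero-filled.
    """
    valid = [m for m in matrices if m.pair_count > 0]
    if not valid:
        raise DegenerateInputError("all co-occurrence matrices are empty")
    per = [_haralick_single(m.P) for m in valid]
    return {k: float(np.mean([d[k] for d in per])) for k in _HARALICK_NAMES}


def _scan_lines(img: np.ndarray, mask: np.ndarray, theta: int):
    """Yield (values, valid) 1-D arrays for each scan line in direction theta."""
    if theta == 0:
        for row in range(img.shape[0]):
            yield img[row], mask[row]
    elif theta == 90:
        for col in range(img.shape[1]):
            yield img[:, col], mask[:, col]
    elif theta == 135:
        h, w = img.shape  # main diagonals, direction (-1,-1) scans the same lines
        for off in range(-(h - 1), w):
            yield np.diagonal(img, off), np.diagonal(mask, off)
    elif theta == 45:
        fi, fm = np.fliplr(img), np.fliplr(mask)  # anti-diagonals
        h, w = img.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(fi, off), np.diagonal(fm, off)
    else:
        raise ValueError(f"theta must be one of {ANGLES}")


def _line_runs(vals: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal constant runs, broken at invalid pixels."""
    n = vals.size
    if n == 0:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    # A new run starts where validity turns on, or the value changes inside a
    # valid stretch.
    prev_valid = np.concatenate(([False], valid[:-1]))
    changed = np.concatenate(([True], vals[1:] != vals[:-1]))
    starts = valid & (~prev_valid | changed)
    start_idx = np.flatnonzero(starts)
    if start_idx.size == 0:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    # Run ends: position before the next start, or before validity turns off.
    valid_idx = np.flatnonzero(valid)
    # For each valid pixel, its run id = number of starts at or before it.
    run_id = np.cumsum(starts)[valid] - 1
    lengths = np.bincount(run_id, minlength=start_idx.size)
    return vals[start_idx].astype(np.intp), lengths.astype(np.intp)


def build_rlm(nucleus: NucleusImage, theta: int, levels: int) -> RunLengthMatrix:
    """Run-length matrix at quantization ``levels`` in direction ``theta``."""
    if levels not in RLM_LEVELS:
        raise ValueError(f"levels must be one of {RLM_LEVELS}")
    q = (nucleus.intensities.astype(np.intp) * levels) // 256
    maxlen = max(nucleus.mask.shape) + 1
    R = np.zeros((levels, maxlen), dtype=np.int64)
    for vals, valid in _scan_lines(q, nucleus.mask, theta):
        lv, ln = _line_runs(np.ascontiguousarray(vals), np.ascontiguousarray(valid))
        np.add.at(R, (lv, ln - 1), 1)
    return RunLengthMatrix(R, theta, levels, int(R.sum()))


def build_rlm_set(nucleus: NucleusImage) -> list[RunLengthMatrix]:
    """The 16 run-length matrices (4 angles x 4 quantizations)."""
    return [build_rlm(nucleus, t, lv) for t in ANGLES for lv in RLM_LEVELS]


def _runlength_single(R: np.ndarray) -> dict[str, float]:
    n_runs = float(R.sum())
    lengths = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    run_per_length = R.sum(axis=0).astype(np.float64)
    run_per_level = R.sum(axis=1).astype(np.float64)
    n_pixels = float(run_per_length @ lengths)
    return {
        "f29": float((run_per_level**2).sum() / n_runs),          # gray-level nonuniformity
        "f30": n_runs / n_pixels,                                  # run percentage
        "f31": float((run_per_length / lengths**2).sum() / n_runs),  # short-run emphasis
        "f32": float((run_per_length * lengths**2).sum() / n_runs),  # long-run emphasis
        "f33": float((run_per_length**2).sum() / n_runs),          # run-length nonuniformity
    }


def runlength_features(matrices: list[RunLengthMatrix]) -> dict[str, float]:
    """Mean of the five Galloway features over matrices with runs."""
    valid = [m for m in matrices if m.total_runs > 0]
    if not valid:
        raise DegenerateInputError("all run-length matrices are empty")
    per = [_runlength_single(m.R) for m in valid]
    return {k: float(np.mean([d[k] for d in per])) for k in _RUNLENGTH_NAMES}
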