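"""Shared fixture builders and independent brute-force oracles.

The oracles deliberately use naive enumeration (python loops over pixels,
sparse dict arithmetic) so they share no code path with the vectorized
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from chromatex import NucleusImage

# ---------------------------------------------------------------------------
# Mask / nucleus builders
# ---------------------------------------------------------------------------


def disk_mask(radius: int, size: int | None = None) -> np.ndarray:
    n = size or (2 * radius + 28)
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def ellipse_nucleus(
    a: float = 30,
    b: float = 24,
    n: int = 96,
    background: int = 180,
    paint=None,
) -> NucleusImage:
    """Noise-free elliptical nucleus; ``paint(img, yy, xx, c, mask)`` adds blobs."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2
    mask = ((yy - c) / a) ** 2 + ((xx - c) / b) ** 2 <= 1
    img = np.full((n, n), 255.0)
    img[mask] = background
    if paint is not None:
        paint(img, yy, xx, c, mask)
    return NucleusImage(np.clip(img, 0, 255).astype(np.uint8), mask)


def convex_blob_nucleus(blob_radius: float = 8.0, blob_intensity: int = 90) -> NucleusImage:
    def paint(img, yy, xx, c, mask):
        img[((yy - c) ** 2 + (xx - c) ** 2 <= blob_radius**2) & mask] = blob_intensity

    return ellipse_nucleus(paint=paint)


def star_blob_nucleus(
    core_radius: float = 7.0, arm_factor: float = 3.0, sharpness: int = 12
) -> NucleusImage:
    """Eight-pointed star blob with arms ``arm_factor`` times the core radius."""

    def paint(img, yy, xx, c, mask):
        d = np.hypot(yy - c, xx - c)
        ang = np.arctan2(yy - c, xx - c)
        r = core_radius * (
            1 + (arm_factor - 1) * np.maximum(0, np.cos(8 * ang)) ** sharpness
        )
        img[(d <= r) & mask] = 90

    return ellipse_nucleus(a=36, b=30, n=110, paint=paint)


def random_textured_nucleus(rng: np.random.Generator, n: int = 8) -> NucleusImage:
    img = rng.integers(0, 256, size=(n, n)).astype(np.uint8)
    mask = rng.random((n, n)) < 0.85
    if mask.sum() < 2:
        mask[:] = True
    return NucleusImage(img, mask)


# ---------------------------------------------------------------------------
# Brute-force texture oracles
# ---------------------------------------------------------------------------

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def bf_glcm_counts(img: np.ndarray, mask: np.ndarray, r: int, theta: int) -> np.ndarray:
    """Symmetrized pair counts by explicit double loop over pixels."""
    dr, dc = (o * r for o in _OFFSETS[theta])
    h, w = img.shape
    counts = np.zeros((256, 256), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dr, x + dc
            if 0 <= y2 < h and 0 <= x2 < w and mask[y, x] and mask[y2, x2]:
                counts[img[y, x], img[y2, x2]] += 1
                counts[img[y2, x2], img[y, x]] += 1
    return counts


def bf_haralick(P: np.ndarray) -> dict[str, float]:
    """The 14 co-occurrence features by sparse direct-formula evaluation."""
    nz = {(i, j): P[i, j] for i, j in zip(*np.nonzero(P))}
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (i, j), p in nz.items():
        px[i] = px.get(i, 0.0) + p
        py[j] = py.get(j, 0.0) + p
    mu_x = sum(i * p for i, p in px.items())
    mu_y = sum(j * p for j, p in py.items())
    var_x = sum((i - mu_x) ** 2 * p for i, p in px.items())
    var_y = sum((j - mu_y) ** 2 * p for j, p in py.items())

    contrast = sum((i - j) ** 2 * p for (i, j), p in nz.items())
    energy = sum(p * p for p in nz.values())
    if var_x > 0 and var_y > 0:
        correlation = (
            sum(i * j * p for (i, j), p in nz.items()) - mu_x * mu_y
        ) / math.sqrt(var_x * var_y)
    else:
        correlation = 0.0
    entropy = -sum(p * math.log(p) for p in nz.values())

    p_sum: dict[int, float] = {}
    p_diff: dict[int, float] = {}
    for (i, j), p in nz.items():
        p_sum[i + j] = p_sum.get(i + j, 0.0) + p
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
    sum_avg = sum(k * p for k, p in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * p for k, p in p_sum.items())
    sum_ent = -sum(p * math.log(p) for p in p_sum.values() if p > 0)
    mu_d = sum(k * p for k, p in p_diff.items())
    diff_var = sum((k - mu_d) ** 2 * p for k, p in p_diff.items())
    diff_ent = -sum(p * math.log(p) for p in p_diff.values() if p > 0)
    idm = sum(p / (1 + (i - j) ** 2) for (i, j), p in nz.items())

    hx = -sum(p * math.log(p) for p in px.values())
    hy = -sum(p * math.log(p) for p in py.values())
    mi = sum(p * math.log(p / (px[i] * py[j])) for (i, j), p in nz.items())
    f37 = mi - max(hx, hy)
    hxy2 = -sum(
        pi * pj * math.log(pi * pj) for pi in px.values() for pj in py.values()
    )
    f38 = 1.0 - math.exp(-2.0 * (hxy2 - entropy))

    # Q via loops over nonzero entries sharing the middle index k.
    cols: dict[int, list[tuple[int, float]]] = {}
    for (i, k), p in nz.items():
        cols.setdefault(k, []).append((i, p))
    sup = sorted(px)
    pos = {i: s for s, i in enumerate(sup)}
    Q = np.zeros((len(sup), len(sup)))
    for k, entries in cols.items():
        for i, pik in entries:
            for j, pjk in entries:
                Q[pos[i], pos[j]] += pik * pjk / (px[i] * py[k])
    if len(sup) < 2:
        f39 = 0.0
    else:
        f39 = float(np.sort(np.real(np.linalg.eigvals(Q)))[-2])

    return {
        "f19": contrast, "f20": energy, "f21": correlation, "f22": var_x,
        "f23": entropy, "f24": sum_var, "f25": sum_ent, "f26": diff_var,
        "f27": diff_ent, "f28": idm, "f36": sum_avg, "f37": f37,
        "f38": f38, "f39": f39,
    }


def bf_runs(img: np.ndarray, mask: np.ndarray, theta: int, levels: int) -> list[tuple[int, int]]:
    """(level, length) of every run, by walking scan lines pixel by pixel."""
    q = (img.astype(int) * levels) // 256
    h, w = img.shape
    if theta == 0:
        lines = [[(y, x) for x in range(w)] for y in range(h)]
    elif theta == 90:
        lines = [[(y, x) for y in range(h)] for x in range(w)]
    elif theta == 135:
        lines = [
            [(y, y - off) for y in range(h) if 0 <= y - off < w]
            for off in range(-(w - 1), h)
        ]
    else:  # 45
        lines = [
            [(y, off - y) for y in range(h) if 0 <= off - y < w]
            for off in range(h + w - 1)
        ]
    runs = []
    for line in lines:
        cur_level, cur_len = None, 0
        for (y, x) in line:
            if mask[y, x] and q[y, x] == cur_level:
                cur_len += 1
            else:
                if cur_len:
                    runs.append((cur_level, cur_len))
                if mask[y, x]:
                    cur_level, cur_len = q[y, x], 1
                else:
                    cur_level, cur_len = None, 0
        if cur_len:
            runs.append((cur_level, cur_len))
    return runs


def bf_runlength_features(runs: list[tuple[int, int]], n_pixels: int) -> dict[str, float]:
    n_runs = len(runs)
    by_level: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for lv, ln in runs:
        by_level[lv] = by_level.get(lv, 0) + 1
        by_len[ln] = by_len.get(ln, 0) + 1
    return {
        "f29": sum(c * c for c in by_level.values()) / n_runs,
        "f30": n_runs / n_pixels,
        "f31": sum(c / (ln * ln) for ln, c in by_len.items()) / n_runs,
        "f32": sum(c * ln * ln for ln, c in by_len.items()) / n_runs,
        "f33": sum(c * c for c in by_len.values()) / n_runs,
    }


# ---------------------------------------------------------------------------
# Other oracles
# ---------------------------------------------------------------------------


def bf_otsu(values: np.ndarray) -> int:
    """Exhaustive between-class-variance scan, plain python."""
    vals = list(values)
    n = len(vals)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = [v for v in vals if v <= t]
        hi = [v for v in vals if v > t]
        if not lo or not hi:
            continue
        w0, w1 = len(lo) / n, len(hi) / n
        var = w0 * w1 * (sum(lo) / len(lo) - sum(hi) / len(hi)) ** 2
        if var > best_var:
            best_t, best_var = t, var
    if best_var < 0:  # constant sample
        return vals[0]
    return best_t
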