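"""Assembly of the full 46-feature vector for one nucleus.

Feature groups (computed lazily, shared intermediates):

* f1-f10    morphometry of the mask
* f11-f18   intensity statistics (f14 is the radial distribution)
* f19-f28, f36-f39  Haralick features over 16 co-occurrence matrices
* f29-f33   Galloway run-length features over 16 run-length matrices
* f34, f35, f40-f43 binarization-sweep complexity features
* f44       chromatin-distribution spreading
* f45, f46  tangential bias over ellipse-aligned quadrants
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from . import bias as _bias
from . import complexity as _complexity
from . import intensity as _intensity
from . import morphometry as _morpho
from . import spread as _spread
from . import texture as _texture
from .io import FEATURE_NAMES, NucleusImage

__all__ = ["extract_features", "extract_table"]

_MORPHO = {f"f{i}" for i in range(1, 11)}
_BASIC_INTENSITY = {"f11", "f12", "f13", "f15", "f16", "f17", "f18"}
_HARALICK = {f"f{i}" for i in (*range(19, 29), *range(36, 40))}
_RUNLENGTH = {f"f{i}" for i in range(29, 34)}
_SWEEP = {"f34", "f35", "f40", "f41", "f42", "f43"}
_BIAS = {"f45", "f46"}


def extract_features(
    nucleus: NucleusImage, names: Iterable[str] | None = None
) -> dict[str, float]:
    """Compute the requested features (default: all 46) for one nucleus.

    Returns a dict keyed by feature name in canonical f1..f46 order.
    Only the intermediates required by the requested subset are built.
    """
    wanted = list(FEATURE_NAMES) if names is None else list(names)
    unknown = [n for n in wanted if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    wset = set(wanted)
    out: dict[str, float] = {}

    geom = None
    need_geom = bool(
        wset & _MORPHO or wset & _SWEEP or "f44" in wset
    )
    if need_geom:
        geom = _morpho.region_geometry(nucleus)
        shapes = _morpho.shape_features(geom)
        out.update(
            {
                "f1": geom.area,
                "f2": geom.perimeter,
                "f3": geom.longest_diameter,
                "f4": geom.shortest_diameter,
                "f5": geom.hull_area,
                "f6": geom.hull_perimeter,
                **shapes,
            }
        )

    if wset & _BASIC_INTENSITY:
        out.update(_intensity.basic_intensity_features(nucleus.masked_values))
    if "f14" in wset:
        out["f14"] = _intensity.radial_distribution(nucleus)

    if wset & _HARALICK:
        out.update(_texture.haralick_features(_texture.build_glcm_set(nucleus)))
    if wset & _RUNLENGTH:
        out.update(_texture.runlength_features(_texture.build_rlm_set(nucleus)))

    if wset & _SWEEP:
        sweep = _complexity.threshold_sweep(nucleus, f10=out["f10"])
        out["f34"] = _complexity.contour_complexity(sweep, out["f2"])
        out["f35"] = _complexity.fractal_feature(sweep)
        out.update(_complexity.convex_complexity_features(sweep))

    if "f44" in wset:
        chrom = _spread.chromatin_image(nucleus)
        G = _spread.gravity_center(chrom)
        out["f44"] = _spread.cds_value(chrom, G, out["f1"], out["f3"])

    if wset & _BIAS:
        frame = _bias.fit_ellipse(nucleus.mask)
        aligned = _bias.align_to_ellipse(nucleus, frame)
        quadrants = _bias.split_quadrants(aligned)
        out["f45"], out["f46"] = _bias.tangential_bias_values(quadrants)

    return {n: float(out[n]) for n in FEATURE_NAMES if n in wset}


def extract_table(nuclei: Iterable[NucleusImage]) -> pd.DataFrame:
    """Feature table (id, label, f1..f46) for a collection of nuclei."""
    rows = []
    for nuc in nuclei:
        rec: dict[str, object] = {"id": nuc.identifier}
        if nuc.label is not None:
            rec["label"] = nuc.label
        rec.update(extract_features(nuc))
        rows.append(rec)
    table = pd.DataFrame(rows)
    meta = [c for c in ("id", "label") if c in table.columns]
    return table[meta + [c for c in FEATURE_NAMES if c in table.columns]]
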