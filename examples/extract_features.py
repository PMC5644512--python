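"""Extract the 46 chromatin-distribution features from one nucleus.

Builds a synthetic high-grade-lesion-like nucleus (dark, irregular,
spread chromatin blobs inside an elliptical mask) and prints a selection
of its features with a note on what each measures.
"""

import warnings

from chromatex import default_class_recipes, extract_features, generate_nucleus

warnings.simplefilter("ignore")

recipe = default_class_recipes()["HSIL"]
nucleus = generate_nucleus(recipe, seed=42, identifier="demo", label="HSIL")
f = extract_features(nucleus)

print(f"nucleus: {nucleus.area} px, label {nucleus.label}")
for name, note in [
    ("f1", "nuclear area (px)"),
    ("f7", "circularity (1 = perfect circle)"),
    ("f11", "mean intensity (dark = chromatin-rich)"),
    ("f19", "co-occurrence contrast (texture coarseness)"),
    ("f32", "long-run emphasis (homogeneous streaks)"),
    ("f34", "contour complexity over the binarization sweep"),
    ("f40", "hull-ratio fill area (small-scale chromatin complexity)"),
    ("f44", "chromatin spreading about its gravity center"),
    ("f45", "tangential bias of intensity across quadrants"),
]:
    print(f"{name:>4} = {f[name]:10.4f}   {note}")
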