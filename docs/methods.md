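# Methods

This note records the models, conventions and numerical choices behind
chromatex, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions were
settled.

## Inputs and conventions

A nucleus is an 8-bit grayscale grid plus a same-shape boolean mask of
the nuclear region (masks are inputs; segmentation is out of scope).
Color input is converted to the luma channel with ITU-R BT.601 weights
(0.299, 0.587, 0.114) — the classic Y of 8-bit YCbCr. Coordinates are
0-based `(row, column)` everywhere. Masks accept 0/1 or 0/255 encodings;
loading rejects masks with fewer than 16 pixels. Multi-component masks
keep the largest 8-connected component with a warning.

## Morphometry (f1–f10)

The outline is the marching-squares contour of the mask at level 0.5.
Raw marching-squares polygons of binary data overestimate smooth
perimeters by ~5–6% (staircase bias); every closed contour is therefore
regularized with a circular moving average of window 5 before
measurement, which brings a rasterized disk's perimeter within 0.3% of
2πr while leaving sub-window contours (single-pixel blobs) untouched.
f1 is the mask pixel count; f2 the smoothed outer-contour length; f3 the
maximum pairwise distance of contour points (computed on hull vertices);
f4 the minimum Feret width over a 1° rotation grid — chosen over the
min-caliper-through-centroid reading, which differs for bent shapes;
f5/f6 come from the convex hull of the contour points. The derived
descriptors are f7 = 4πf1/f2², f8 = f3/f4, f9 = πf3²/(4f1), f10 = f2/f6.
With these estimators the isoperimetric bound f7 ≤ 1 and the hull bound
f10 ≥ 1 hold within a rasterization tolerance of a few percent.

## Intensity statistics (f11–f18)

Computed on the masked pixel sample. f12/f13 are read literally as the
counts of pixels attaining the sample maximum/minimum (not local-extrema
counts — both readings exist in the older literature; the literal one is
fixed here). f15 is moment skewness m₃/m₂^1.5, f16 excess kurtosis
m₄/m₂² − 3, f17 the coefficient of variation with sample (n−1) SD. f18
is the fraction of pixels in the top 20% of the observed intensity range
[min + 0.8(max−min), max] — a self-consistent reading of the "upper 20
percentile ratio", whose original definition is not restated in the
sources this feature set descends from. f14 (radial distribution) is the
mean intensity of "center" pixels (within 0.5·r_eq of the mask centroid,
r_eq = √(f1/π)) minus the mean of the remaining "periphery" pixels; the
ring geometry is a fixed convention here. Constant samples take the
conventions f15 = f16 = f17 = 0, f18 = 1.

## Texture (f19–f33, f36–f39)

Co-occurrence matrices are built at full 256 gray levels for the 16
displacements r ∈ {1,2,4,8} pixels × θ ∈ {0°,45°,90°,135°}; a pair
counts only when both pixels are masked; matrices are symmetrized and
normalized (classical Haralick practice). Runs for the run-length
matrices are maximal constant-level segments along scan lines in the
four directions, with intensities quantized as ⌊I·levels/256⌋ for
levels ∈ {256,16,4,2}; a run never crosses an unmasked pixel. Features
are computed per matrix and averaged over the 16 matrices (features
averaged, not matrices); matrices with no pairs/runs — masks smaller
than the displacement — are dropped from the average rather than
zero-filled. Logarithms are natural; 0·log 0 = 0.

Three information measures deliberately diverge from Haralick's classical
definitions and follow the printed forms this feature set uses:
f37 = MI − max(HX, HY) with MI the mutual information of P; f38 =
1 − exp(−2(HXY2 − HXY)) **without** the classical square root; f39 is the
second-largest eigenvalue of Q(i,j) = Σₖ P(i,k)P(j,k)/(pₓ(i)p_y(k)),
again without the square root. Cells of Q with empty marginals
contribute zero (the computation is restricted to the marginal support).
Sum variance (f24) uses the sum average as its center — the common
correction of a well-known typo in the original formula table.
Correlation (f21) of a constant image is 0 by convention.

## Binarization sweep (f34, f35, f40–f43)

Foreground at threshold i is the masked pixels with intensity ≤ i:
chromatin stains dark, so complexity is measured on dark regions, and
the foreground grows monotonically with i. The sweep computes, per
threshold, the summed contour perimeter L(i) of all foreground
components (hole boundaries included), the convex-hull perimeter LC(i)
of the joint foreground contour points, the normalized hull ratio
Lr(i) = L(i)/(LC(i)·f10), and the box-counting dimension D(i) of the
foreground boundary pixels. Using contour points for both L and LC
keeps the two on one convention and avoids a zero-perimeter hull for
single-pixel foregrounds. Since the foreground only changes at intensity
values present in the mask, geometry is computed once per distinct
foreground and replicated across constant ranges. Thresholds with empty
foreground stay undefined and contribute nothing downstream.

Note that L(i) ≥ LC(i) is guaranteed only for connected foregrounds; a
scattering of tiny specks has a joint hull far longer than its summed
contours. Such thresholds have Lr < 1 and do not touch f40–f43.

Box counting uses sizes {1,2,4,…,64} px, anchored at the point set's
bounding-box corner, dropping sizes above a quarter of the set's extent
(at least the three smallest sizes are kept); the dimension is the OLS
slope of log(count) vs log(1/size). Anchoring and the size cap are
required for the estimator to hit the textbook values (≈2 for a filled
square, ≈1 for a line) at these image sizes; with origin-anchored boxes
up to 64 px the slope is flattened by boxes much larger than the object.

f34 sums (L(i)/f2 − 1) over thresholds where L(i) > f2; f35 is max D(i);
f40 sums (Lr(i) − 1) over Lr(i) ≥ 1; f41/f42/f43 count thresholds with
Lr(i) ≥ 1.1/1.2/1.3 (so f41 ≥ f42 ≥ f43 structurally).

## Chromatin spreading (f44)

The threshold Th separating dark chromatin from lighter background is
the between-class-variance maximizer of the masked 256-bin histogram
(Otsu's discriminant criterion), found by exhaustive scan with ties
toward the smaller threshold; a constant sample returns its own value.
The chromatin image is I′(Z) = 255 − I(Z) − Th where I(Z) + Th < 255,
else 0. f44 is the I′-weighted second moment about the I′-weighted
centroid G, scaled by 1/f1 and 1/f3²; it is 0 iff the chromatin mass is
a point, translation-invariant, and approximately scale-invariant.
Zero-mass chromatin images fall back to the mask centroid with f44 = 0.

## Tangential bias (f45, f46)

The mask is fitted to an ellipse from its second central moments (axes
4·√eigenvalues — the moment fit is robust for blob-like masks and
standard in cytometry, unlike contour least squares). The nucleus is
rigidly rotated/translated so the ellipse center lands on the canvas
center with the major axis vertical (bilinear intensity, nearest-neighbor
mask resampling), then cut into four quadrants at the canvas axes. The
canvas is even-sized, putting the cutting axes between pixels: the
quadrants always partition the mask exactly, and a mirror-symmetric
nucleus yields exactly mirrored quadrants (hence exactly zero bias) —
with axes through pixels those two properties cannot hold at once.

For a feature ft the bias is gt = |SD(ft,1..ft,4)/mean(·)| with sample
(n−1) SD — fixed by the closed form (m,0,0,0) → gt = 2. Quadrant
features that need whole-nucleus normalizers (f40–43 use f10, f44 uses
f3) treat each quadrant as its own region. An empty (or < 8 px) quadrant
is dropped from gt with a warning; two or more missing is an error; a
zero mean gives gt = 0 by convention. f45 averages the intensity-related
biases (g11, g18, g24, g36), f46 the run-length biases (g29–g32). The
full-vector extraction computes exactly these eight quadrant features;
the generic `quadrant_bias` supports all t ∈ {11, 12, 18..44}.

## Cohort statistics

Features are min-max normalized per column (constant columns → 0.5 with
a warning; the map is idempotent). The correlation screen reports
feature pairs in the bands |ρ| ≥ 0.95 and 0.90 ≤ |ρ| < 0.95 (sample
Pearson; the n−1 choice is cosmetic since the ratio cancels it). Group
comparisons use one-way fixed-effects ANOVA at α = 0.01 across the seven
classes and a two-sided **Welch** t-test (reactive MET/REG vs neoplastic
LSIL/HSIL/CIS/SCC) with stars at 0.05/0.01 — Welch because the pooled
groups are unbalanced; no multiple-testing correction is applied, the
results being reported per feature.

## Stepwise SVM protocol

ADASYN oversamples every class to a common target **before** selection
and cross-validation, as the protocol orders it: synthetic rows are
convex combinations x + λ(x' − x) of same-class neighbors (k = 5), with
per-sample allocation proportional to the fraction of other-class
neighbors (largest-remainder rounding makes the target exact) and
classes below k+1 samples falling back to random-pair interpolation.
Because balancing precedes CV, synthetic siblings may cross folds; the
resulting optimism is a property of the protocol and is not silently
"corrected".

Per class pair, floating selection alternates forward additions (add the
feature maximizing stratified k-fold CV accuracy; repeated while the
best accuracy strictly improves; the first feature is added
unconditionally), backward removals (remove while a removal strictly
improves), and re-optimization of (kernel, cost) over the grid
W = {linear, RBF} × {0.1, 1, 10, 100} with RBF γ = 1/m — a conventional
grid, configurable, since only the grid's existence is specified by the
protocol. Ties break toward the smaller feature index, then the earlier
grid entry (linear first, costs ascending). A full cycle without
improvement terminates. Folds are stratified to avoid empty-class folds
at small n, and are reduced with a warning when a class is smaller than
the fold count.

Multiclass accuracy (MCV) retrains the 21 pairwise models per fold and
lets them vote per test sample; ties go to the larger summed
|decision-function| margin, then the smaller class index in the
canonical NOR..SCC order. The evaluation loop reshuffles the rows per
restart, reruns selection, scores each restart by the mean of several
MCV runs on fresh fold partitions (models fixed per restart), and
reports the repeat-level accuracies of the best restart. Everything is
driven by one master seed; two runs with the same seed are bit-identical.

Family comparison evaluates each feature family under **common random
numbers** (identical shuffles/folds), so identical families score
identically, and tests each against the control with Dunnett's
many-to-one criterion. Critical values of the max-|t| null come from
Monte-Carlo simulation (default 100 000 draws) of the group means
(normal) and pooled variance (χ²), which is exact under normality; with
two groups this reproduces the two-sided t critical value.

The **permutation sanity check** re-scores the models selected on true
labels against permuted labels via MCV. Rerunning the selection on
permuted labels would instead measure selection bias (at n = 280 it sits
several points above chance), which is a property of any
select-then-validate protocol, not of the classifier.

## Synthetic nuclei

The generator emulates what the features probe, not photorealism: an
elliptical mask (random orientation), background at a fixed intensity
plus Gaussian noise (SD 3, clipped), and dark chromatin blobs filled at
a constant intensity. Blob outlines are perturbed with 3–8-harmonic
periodic radial noise whose relative amplitude is the
`boundary_irregularity` knob — chosen so the hull-ratio bands 1.1/1.2/1.3
are directly exercisable. Blob centers are placed per `quadrant_weights`
in the ellipse frame at `radial_spread` of the local ellipse radius.
The seven default recipes grade size, blob count, blob darkness,
irregularity, spread and quadrant bias from NOR to SCC, mirroring the
qualitative ordering reported for real cervical nuclei; they are a test
harness, not a biological claim. Per-nucleus seeds derive from a master
seed; images are bit-reproducible.

What the generator does **not** model: staining variability, cytoplasm
and overlapping cells, nucleoli as distinct bright-rim structures,
optical blur, and correlated texture inside chromatin blobs. Passing
tests therefore demonstrate the correctness and discriminative behavior
of the features on controlled geometry, not clinical performance; the
benchmark's near-perfect accuracy reflects the deliberately well
separated recipes and the protocol's oversample-then-CV optimism.

## Problem sizes and degenerate inputs

The test suite and the acceptance script run the benchmark at 20
nuclei/class on 96-px canvases, ADASYN target 40, 5-fold CV, 3 restarts
and 5 MCV repeats — sizes chosen so the full pipeline exercises every
code path in minutes on one CPU; all protocol parameters scale up via
arguments (the defaults of `evaluate` mirror the full protocol: 10-fold,
40 restarts, 50 repeats, target 200). Degenerate inputs follow the
conventions stated above (constant samples, empty quadrants, empty
sweeps), each with a warning rather than silent repair.
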