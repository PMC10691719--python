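# Methods

This note documents the models, parameters and design choices behind
`myelinseg`, and what the synthetic phantoms do and do not demonstrate.

## Preprocessing

Images load as floats scaled by the integer dtype maximum (255 or 65535).
Normalisation is a contrast stretch with a saturated-pixel budget split
equally between tails: with `n` pixels and fraction `f` (default 0.01), the
`k = floor(n·f/2)`-th smallest and largest intensities become the clip
bounds, then values map affinely to [0, 1]. With distinct intensities
exactly `k` pixels saturate per tail. A constant image maps to zeros with a
warning rather than raising, so batch runs proceed. Downsampling is
block-mean over `factor × factor` tiles (anti-aliased, conserves total
intensity) and multiplies the pixel size by the factor; trailing
rows/columns that do not fill a block are cropped with a warning.

## Pixel classification (autocontext)

The feature bank computes, per scale σ in (0.3, 0.7, 1.0, 1.6, 3.5, 5.0,
10.0, 15.0, 30.0, 50.0): Gaussian smoothing (intensity); Laplacian of
Gaussian, Gaussian gradient magnitude and a difference of Gaussians between
σ and 0.66σ (edge); and the two eigenvalues each of the structure tensor
and the Hessian (texture). The smallest scale contributes smoothing only;
scales above half the image side are skipped with a warning. All filters
use reflect padding so a constant image yields exactly zero derivative
responses. Channel order is fixed and exposed programmatically.

Both classifier passes are random forests (100 trees, unlimited depth,
√p features per split, seeded, single-threaded for reproducibility).
Stage A trains on sparse scribbles with four classes — compact myelin,
axoplasm, membrane, mitochondria — and requires at least one labelled pixel
per class. Stage B trains on the same scribbles with mitochondria
relabelled to axoplasm (preventing organelle-shaped holes in axon
instances); its input is the raw feature bank plus stage A's four
probability channels and one Gaussian smoothing of each at every scale.
The predicted 3-channel stack is renormalised to sum to one per pixel.

## Candidate extraction and object classification

Axoplasm candidates follow the fixed operator order: Gaussian smoothing of
the axoplasm channel at σ = 2.0, binarisation at ≥ 0.6, 8-connected
labelling, rejection of components under 10 px, and renumbering in
raster-scan order of each component's first pixel (deterministic
tie-break). The object classifier is a random forest over shape
(area, perimeter, circularity, convex area, solidity, eccentricity,
equivalent diameter, extent) and intensity-distribution features (mean, SD,
min, max, five quantiles, a 10-bin histogram); location features are
deliberately excluded so the model is translation invariant. Training
labels come from an object-scribble raster (codes: large axon, small axon,
inner tongue) by majority vote per candidate; unlabelled candidates are
excluded, and if a class has no labelled exemplars the model simply trains
on the classes present (the unannotated kinds are handled downstream by
overlap gating).

## Staged segmentation

**Stage 1.** The myelin mask is the per-pixel probability argmax
(no extra threshold parameter), optionally closed with a radius-1 disk
(default on) to seal hairline gaps. Inner-region candidates are the
connected components of the inverted mask, labelled with 4-connectivity —
the topological dual of the 8-connected mask, so a diagonally connected
ring still seals its hole. A candidate is selected iff it avoids the image
border, its area lies in `[min_area_px, max_area_fraction · image area]`
(defaults 50 px and 0.05 — calibrated for ~1024² frames; small test frames
need a wider window) and its mean axoplasm probability is ≥ 0.4. Everything
else is kept as a rejected candidate; nothing is silently dropped, so batch
curation can recover any component.

**Stage 2.** Selected inner regions expand through the myelin mask by
uniform-cost geodesic flooding: a level-synchronous multi-source BFS with
8-connectivity in which each reachable myelin pixel joins the seed at the
smallest geodesic distance, ties going to the lower seed label. This is a
deterministic special case of a marker-controlled watershed whose priority
surface is flat; it is exactly checkable against an independent per-seed
BFS oracle. Myelin unreachable from any seed stays background — a missed
seed therefore lets neighbouring fibres absorb adjacent myelin, which is
the expected failure mode that curation at Stage 1 repairs.

**Stage 3.** An axon-classified object is selected iff at least half its
area (configurable) lies inside one single inner region; it inherits that
fibre's id. Inner-tongue objects become rejected candidates; objects
overlapping no inner region (cells, unmyelinated axons, background
fragments) are eliminated. If several axons land in one inner region only
the largest stays selected. Selected axons are then repaired with
`fill_holes` by default (mitochondria punch holes in axoplasm candidates);
convex hull and closing are opt-in alternatives. All corrections can only
grow the region.

**Curation.** A JSON file per stage lists labels to accept or reject and
polygons (pixel coordinates, even-odd fill over pixel centres) to add as
fresh selected candidates. Accept/reject lists must be disjoint; polygons
with fewer than three vertices or self-intersections are refused.

## Hierarchy and morphometry

Inner and fibre regions are reduced to their largest connected component
(axons may stay composite); containment is enforced by clipping inner to
fibre and axon to inner; an entry without an axon optionally duplicates its
inner region as the axon (flagged), modelling a shrunken tongue; axons
attach to the inner region of maximal pixel overlap (tie: lower label).
Border-touching fibres are measured and flagged, never dropped — exclusion
happens only in the agreement analysis. Areas are pixel counts ×
pixel_size², diameters are circle-equivalent, so g_myelin =
√(A_inner/A_fibre) identically and the tongue index g_myelin − g_axon is
0 exactly when the axon duplicates the inner region. Eccentricity comes
from the fibre region's normalised second central moments (0 = circle).
The semantic mask partitions each fibre into axon, inner tongue
(inner − axon) and compact myelin (fibre − inner).

## Evaluation protocol

Instance matching is greedy one-to-one in descending IoU (ties: lower
target, then lower prediction label), restricted to thresholds ≥ 0.5 where
a target can overlap at most one prediction above threshold — there greedy
matching equals the exhaustive optimal assignment, which the tests verify
by brute force. Precision, recall and F1 (equal by construction to
2TP/(2TP+FN+FP)) are averaged over thresholds 0.5–0.9 in steps of 0.05; the
mean Jaccard is the mean over target objects of their best IoU against any
prediction. Agreement between two hierarchies first removes border-touching
fibres from both sides, pairs the rest at IoU ≥ 0.5, then computes Lin's
CCC with 1/n moment estimators and a 95% CI via the Fisher z-transform with
Lin's asymptotic standard error, and Bland–Altman bias (prediction − target)
with 1.96·SD(n−1) limits of agreement. False-negative/-positive rates are
pooled across images with border fibres excluded from the denominators.

## Synthetic phantoms

Each myelinated fibre is a nest of three similar ellipses. The axon has
circle-equivalent radius drawn lognormal (median ≈ 10 px, σ = 0.25, clipped
to 7–26 px) with axis ratio uniform in [1, 2]; the inner region is the axon
scaled by s = 1/√(1 − t) where the tongue fraction t ~ Beta(2, 8); the axon
is offset along the major axis to internal tangency, δ = (s−1)·a, so the
tongue is a simply connected crescent. The fibre is the inner region scaled
by 1/g with the target myelin g-ratio g drawn from a normal (0.72, 0.07)
truncated to [0.55, 0.85] — matching the wide diameter and g-ratio spread
of remyelinating corpus callosum. Intensities: extracellular 0.80,
axoplasm 0.75, tongue 0.65, membrane 0.35, myelin 0.15, mitochondria 0.25;
Gaussian blur σ = 0.7 px then additive noise (SD 0.05) clipped to [0, 1] —
separable but noisy, so classifier tests are non-trivial. Fibres are placed
by rejection sampling with a 3-px dilated-footprint clearance and a border
margin; unmyelinated axons (Binomial(n_fibres, 0.2) extra placements) are
painted but absent from the ground truth, exercising the Stage-3
myelinated-only gate. The truth table records analytic areas and g-ratios
from the generating geometry, never from the rasters.

Ideal probability stacks one-hot encode myelin / axoplasm (axon + tongue) /
everything else, with the 1-px axon boundary assigned to the third channel,
then blur each channel (default softness 0.5 px, kept small so the thinnest
rasterised rings — ≈ 1.5 px at r = 7 px, g = 0.85 — remain argmax-dominant)
and renormalise. A perturbation utility re-draws the class of a fraction of
pixels before softening, for robustness experiments.

**What the phantoms do not emulate:** real TEM texture (lamellae, staining
gradients, knife marks), myelin debris and degenerated dark axons, touching
or overlapping fibres, out-of-focus regions, and intensity drift across the
field. Passing the phantom-recovery tests therefore demonstrates the
correctness of the pipeline's logic and measurement chain, not segmentation
accuracy on real tissue.

**Known behaviour.** From ideal stacks, the axoplasm dip across the 1-px
axon membrane lands near the 0.6 candidate threshold after σ = 2 smoothing,
so axon/tongue separation at extraction is partial: some candidates split
cleanly, others span the whole inner region (then the measured tongue index
underestimates the true one). Axon detection at IoU 0.5 is unaffected since
even a merged candidate overlaps the true axon by 1 − t, which exceeds 0.5
for essentially all tongue fractions drawn from Beta(2, 8).

## Numerical choices and degenerate inputs

- Ties everywhere resolve to the lower label; candidate numbering follows
  raster-scan order of first pixels — all outputs are bit-reproducible for
  fixed seeds and inputs.
- IoU of two empty regions is an error (undefined), not 0.
- Thresholds compare with ≥; component labelling of foreground is
  8-connected, of mask holes 4-connected.
- Zero-variance inputs to the CCC and matching below IoU 0.5 are rejected
  with explicit errors.
- Empty candidate sets, empty hierarchies and zero-fibre phantoms flow
  through every stage producing empty-but-valid outputs.

## Problem sizes used in the automated checks

End-to-end recovery runs a 50-fibre phantom on a 512² frame (fibre
diameters ≥ 20 px, where discretisation keeps the measured myelin g-ratio
within ±0.02 of the analytic value); the classifier loop trains on one
sparsely scribbled 256² phantom (200 px per class) and evaluates on four
held-out phantoms; formula and flooding identities are fuzzed at 1000 and
200 cases, hierarchy invariants at 500. These sizes make the full suite and
the acceptance script complete in a few minutes on one CPU while keeping
every statistical margin comfortable.
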