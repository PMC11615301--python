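# Methods

## Scope and data model

All analysis is two-dimensional, performed on maximum-intensity
projections (MIPs) of wide-field fluorescence z-stacks; z-stacks are
projected on read and the z-step (default 0.25 µm) is kept only as
metadata. A *fragment* is one 8-connected component of the binary
mitochondrial mask; 8-connectivity is used for component labelling
throughout, matching the convention of common particle-analysis tools.
Physical calibration is µm per pixel, isotropic, with precedence
explicit config > TIFF resolution tags > 1.0 µm/px with a logged
warning. Binary masks are written as 8-bit {0, 255} TIFFs and any
nonzero pixel is read as foreground, so masks from other tools ingest
cleanly. Cell label masks are consumed, never computed: cell
segmentation is the job of an external tool, and any integer-labelled
TIFF is accepted.

## Threshold segmentation

Preprocessing is rolling-ball background subtraction (default radius
50 px) followed by a square median filter (default radius 1, i.e. 3×3),
with output clipped at zero; both steps are identity at radius 0. The
sweep thresholds the preprocessed image at each level `t` with the
inclusive rule `img ≥ t`, applies a binary opening (disk radius 1 by
default) and removes components smaller than `min_fragment_area_px`
(default 4 px²). The default threshold grid is 20 evenly spaced levels
between the 70th and 99.5th intensity percentiles of the preprocessed
image; an explicit list or a min/max/step range overrides it. Because
expert visual threshold selection is not reproducible, three
deterministic selection modes replace it: `auto_otsu` (candidate nearest
the Otsu threshold; parameter-free default), `max_dice_vs_truth`
(requires a reference mask; ties go to the lower threshold), and
`manual_index`.

## Fragment morphology

Measurements follow the particle-analysis conventions: area is pixel
count × pixel_size²; perimeter uses the Crofton 4-direction estimator
(more isotropic than boundary-step counting; a `boundary` mode is kept
as a config switch, and absolute perimeter-derived values may differ
from other tools' estimators by a few percent — comparisons should be
property-based, not digit-exact). Ellipse axes come from the second
central moments, rescaled so the ellipse area equals the fragment area.
Circularity 4πA/P² and roundness 4A/(π·major²) are clamped at 1.0
because discretisation can push the raw ratio slightly above the
continuous bound. Solidity divides the area by the convex-hull area of
the pixel *squares* (computed on a 2× upsampled grid), so a single
pixel is convex with solidity exactly 1 rather than dividing by zero.

## Skeleton metrics

Fragments are thinned with the standard 2D thinning algorithm; a
cleanup pass deletes one pixel from any residual fully filled 2×2 clump
whenever that preserves the component count and Euler number, so
downstream accounting can assume a genuine unit-width skeleton (inputs
containing a filled 2×2 block are rejected). Endpoints are skeleton
pixels with exactly one 8-neighbour; junction pixels have three or
more, and touching junction pixels are merged into one junction cluster
to stop thinning artefacts inflating the junction count. Branches are
the edges of the graph whose nodes are endpoints and junction clusters;
an isolated cycle is one branch; an isolated single pixel is treated as
a degenerate filament (one branch, one endpoint). Step lengths are 1
orthogonally and √2 diagonally, with diagonal steps shortcut by an
orthogonal skeleton pixel dropped (m-connectivity) so staircases are
not measured twice.

Fragment length defaults to the geodesic diameter of the skeleton
(longest shortest path; exact over endpoint pairs, double-sweep for
endpoint-free cycles), which side branches inflate less than the total
skeleton length; `total` mode is available, and both values are
reported per fragment. Skeletons of fewer than 2 pixels fall back to
the area-equivalent diameter 2·√(A/π). No end-erosion compensation is
applied: thinning shortens each free tube end by roughly half the tube
width, a documented bias of order width/2 per end.

The filamentous factor is FF = (ΣJ + ΣB)/ΣE over all fragments of a
cell (default aggregation level; per-image available). The denominator
is guarded with max(ΣE, 1) so that all-loop skeletons — for which the
quantity is otherwise undefined — still yield a finite value; an empty
fragment set reports NaN. Raw (ΣJ, ΣB, ΣE, n) sums are exposed so any
alternative branching statistic can be formed downstream.

### Local thickness

Thickness at pixel p is the diameter of the widest disk lying entirely
in the foreground and containing p. Distances to background are kept as
exact integer squared Euclidean distances (from the EDT's
nearest-background indices), every containment comparison is on
integers, and the diameter is reported as 2·(√R² − 0.5)·pixel_size —
the 0.5 px measures to the near *edge* of the nearest background pixel
rather than its centre, so an n-pixel-wide strip reads exactly n (the
plain 2·EDT convention overestimates odd widths by one pixel). Because
the arithmetic is integer-exact, an exhaustive search over all candidate
disk centres reproduces the fast implementation bit for bit; that
equivalence is asserted in the test suite on fixtures up to 64×64.

## Cell binding

Each fragment is assigned whole to the cell with maximal pixel overlap
(ties to the lower label); fragments overlapping no cell are orphans,
excluded from per-cell statistics but tallied so that per-cell areas
plus orphan area always partition the total fragment area. Because a
fragment can spill across its cell's boundary, the area ratio can
exceed 1 when masks disagree; the `clip_fragments_to_cells` flag counts
only pixels inside the assigned cell and guarantees ratio ≤ 1. Cells
touching the image border are kept by default (`exclude_border_cells`
is available).

## Evaluation and aggregation

Dice is dc = 2TP/(2TP+FP+FN) on exact pixel counts, with a per-pixel
confusion map; two empty masks score 1.0 by convention, so a correct
empty prediction is not penalised. Whole images are compared (no
sub-region averaging). Per-image aggregation is the unweighted mean of
each parameter over the image's fragments (an area-weighted variant is
a flag); method agreement is the Pearson correlation of paired
per-image means over ≥ 3 images, NaN under zero variance. Group-level
hypothesis testing is deliberately out of scope — the CSV outputs are
tidy inputs for any statistics package.

## Phantom generator

The generator emulates the three biological regimes plus a noisy
acquisition scenario on a 512×512, 16-bit canvas: cells are
non-overlapping random ellipses (semi-axes 40–60 px, roughly a yeast
cell at ~0.08 µm/px); **tubular** mitochondria are smooth wobbled arcs
hugging the cell cortex with 1–2 inward side branches per fragment
(2–3 fragments per cell); **spherical** mitochondria are well-separated
disks 1.1–1.7× the tube width (5–8 per cell, mimicking swollen
stress-collapsed organelles); **web** mitochondria are a cortical ring
plus 2–3 chords, giving skeletons with cycles; **noisy_background**
adds dim autofluorescent unlabelled cells (12 % of peak, blurred) and
bright artefactual spots placed disjoint from the truth. Tubes render
with a Gaussian cross-section (default FWHM 5 px, a diffraction-limited
mitochondrial tubule at wide-field sampling; peak 20 000 counts over a
2 000-count baseline with σ = 800 Gaussian read noise, a realistic ~25:1
peak-to-noise for mtGFP imaging). Ground truth is fixed *before* noise
by thresholding each fragment's profile at half peak (FWHM convention),
which makes the true mask width equal the generating FWHM, and overlaps
resolve to the strongest profile. All randomness descends from
`spec.seed` through per-purpose and per-cell substreams: output is
bit-identical for a fixed spec, and raising `n_cells` leaves existing
cells untouched.

What the phantoms do *not* model: a real point-spread function (the
Gaussian cross-section is an idealisation), out-of-focus haze and
z-dependent blur, photon shot noise (noise is additive Gaussian, not
Poisson), uneven illumination, and touching or overlapping cells.
Passing the recovery suites therefore shows the measurement chain is
correct on idealised tubes/spheres/webs of known geometry, not that
segmentation will reach the same accuracy on real micrographs.

## Problem sizes and numerical choices

The test and acceptance suites run phantoms at their default 512×512
size (256×256 with 2–3 cells where a threshold sweep with rolling-ball
preprocessing is involved), which keeps the full suite under a minute
while leaving dozens of fragments per condition. Recovery tolerances
follow the known biases: median local thickness within 15 % of the
generating FWHM (half-max truth masks quantise the width); geodesic
length within 10 % of the generating centerline for unbranched tubes at
least 10× longer than wide (end erosion of ~width/2 per end); the
low-noise sweep must contain a candidate with Dice ≥ 0.9 (a threshold
grid step changes the recovered tube width by a predictable factor
√(ln(I/t)/ln 2)). Row order in every CSV is deterministic (image name,
then label), floats are written at full precision, and rerunning a
pipeline with identical inputs and config produces byte-identical
tables.

## Known limitations

2D analysis understates the length and branching of structures that
wander in z; the filamentous factor is undefined for loop-only networks
and is guard-railed rather than extended; skeleton-based lengths carry
the end-erosion bias noted above; Crofton perimeters differ a few
percent from boundary-weighted estimators, so circularity comparisons
across software should be relative, not absolute; and the expert
threshold choice of interactive workflows is replaced by deterministic
rules that may pick a slightly different candidate than a human would.
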