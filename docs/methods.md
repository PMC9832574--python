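# Methods

This note documents the models, conventions and parameter choices behind
`microglia-morph`, in the spirit of a methods section: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do not
establish.

## Imaging model and units

The package analyses two-channel 2-D frames: a red cytoplasmic reporter
marking microglia and a green nucleic-acid stain (SYTOX) marking debris
particles. Multi-z acquisitions are reduced by per-pixel maximum projection
before analysis. All physical quantities are micrometres (lengths) and
square micrometres (areas), converted through the lateral pixel size; the
default pixel size is 0.758 µm, matching a 20× confocal acquisition at
zoom 2. The only rule expressed in pixel units is the incomplete-cell
filter (below), because it compares a pixel count against a perimeter.

## Segmentation

**Smoothing.** Perona–Malik anisotropic diffusion with exponential
conductance `g(s) = exp(-(s/K)²)`, explicit step `dt = 0.2`, reflecting
boundaries. The update is written in flux form: the flux between each pixel
pair appears antisymmetrically in both pixels' updates, so total intensity
is conserved to floating-point precision. Defaults: 10 iterations,
conductance `K = 20` intensity units. Edges with contrast well above `K`
diffuse negligibly, which is the property the segmentation relies on.

**Relative threshold.** Foreground is every pixel strictly brighter than
`factor ×` the background estimate, default factor 1.5. The background is
estimated as the mode of a 256-bin intensity histogram of the smoothed
frame: at the low microglia densities typical of neuron–glia cultures the
background is the dominant intensity by a wide margin, making the mode a
robust scale-free estimate, and a ratio threshold keeps working when
reporter expression is faint. A perfectly flat frame has no contrast; the
result is an empty foreground plus a warning.

**Labelling and filters.** Components are labelled with 8-connectivity
(matching common ImageJ behaviour) and relabelled 1..K in raster-scan order
of their first pixel, for bit-reproducibility. Two filters follow, with
defaults chosen for cultured microglia: components smaller than 200 µm² are
debris; components whose *total* skeleton length exceeds 450 µm are merged
clumps or astrocyte-like arbors. A switch (`skeleton_length_mode`) filters
on the longest single branch instead, since either convention is defensible.

**Skeleton length convention.** Shapes are thinned to a unit-width skeleton
(2-D thinning); length is the sum of inter-pixel step lengths over the
skeleton's 8-adjacency graph — 1 per axial step, √2 per diagonal step, each
adjacent pair counted once — times the pixel size.

**Mask edits.** Interactive curation is replaced by scripted edit records:
a *split* removes a rasterized polyline from one label and relabels its
pieces; a *merge* gives several labels one id. A split polyline that misses
its label is a warning-level no-op.

**Tracking.** Greedy maximal-overlap linking: a cell at frame *t* inherits
the id of the frame *t−1* cell it overlaps most, accepted when the overlap
is at least 20% of the smaller of the two areas; matching is injective per
frame (descending overlap) and unmatched cells get fresh, never-reused ids.
The rule assumes displacement per frame is small relative to cell size,
which holds at the few-minute sampling the assay uses.

## Morphometry

Base features per labelled cell: Area, ConvexArea (rasterized convex hull),
Perimeter, best-fit-ellipse half-axes (image moments), GeodesicDiameter,
LargestInscribedCircleRadius (Euclidean distance-transform maximum),
RadiusAtBrightestPoint (distance-transform value at the cell's brightest
pixel; raw intensity by default, a switch accepts a smoothed image),
skeleton total length / longest branch / branch-point count, four intensity
summaries, centroid, and the border-contact pixel count.

Conventions that the derived ratios inherit, stated explicitly:

* **Perimeter** is the weighted boundary-step estimate used by
  `skimage.measure.regionprops` (axial 1, diagonal √2, corner pairs
  (1+√2)/2).
* **Geodesic diameter** is the longest shortest-path between any two cell
  pixels walking inside the mask. The pixel graph uses axial (1), diagonal
  (√2) and knight-move (√5) steps — the knight moves cut the chamfer
  metrication error from ~8% to ~2% of Euclidean length — and knight edges
  require the two flanking cells, so paths cannot cut across background.
  The value is computed by multi-start farthest-point iteration (Dijkstra
  sweeps from the shape's extreme pixels); it is always a realized path
  length and matches brute-force all-pairs distances on every small shape
  tested.
* **Skeleton statistics** are computed on a *canonical orientation* of the
  cell patch: the lexicographically smallest of its eight axis-aligned
  rotations/flips. Thinning algorithms are not exactly equivariant under
  90° rotation; canonicalization makes the skeleton features exactly
  invariant under integer translation and axis-aligned rotations and flips,
  at no cost in meaning. Branch points are 8-connected clusters of skeleton
  pixels with ≥3 skeleton neighbours (a rasterized junction can span more
  than one pixel); branches are the components left after removing junction
  pixels. A degenerate single-pixel skeleton (a compact disk can thin to one
  pixel) is assigned one pixel of length so that skeleton-based ratios stay
  defined for round cells — such cells then have a large but finite
  Thickness rather than a missing value.

The ten derived ratios are applied literally as printed in the morphometry
table (README). Two are worth flagging: *Roundness* and *Circularity* lack
the π/4π normalisations of their classical namesakes — the literal formulas
are kept because the classifier only needs monotone transforms — and
*Branchiness* (branch count / geodesic diameter) carries units of 1/length,
so it is the one derived feature that changes under pixel-size rescaling.
A zero denominator (degenerate geometry) leaves the ratio missing rather
than zero, so degenerate cells are flagged, not silently absorbed.

**Incomplete cells.** A cell whose border-contact count exceeds 1% of its
perimeter *in pixels* is incomplete and removed before classification
(strictly above: a cell exactly at the limit is kept). This avoids
misclassifying cells truncated by the field of view.

## Classification

Features are z-scored per column on the training cells. By default all base
and derived *shape* features enter the embedding; intensity summaries,
centroids and border contact do not (they reflect acquisition rather than
morphology), and a parameter widens or narrows the set. Supervised UMAP
(2 components, 15 neighbours, min_dist 0.1, categorical target, target
weight 0.6, fixed random state) learns a projection in which annotated
classes separate; unannotated cells are projected through the learned
transform without re-fitting. HDBSCAN (min cluster size 10, exposed) finds
density clusters in the combined 2-D cloud; each cluster takes the most
frequent annotation among its annotated members and every member inherits
it. Noise points, annotation-free clusters and tied votes are `unassigned`
— conservative by design, since downstream composition statistics can carry
an explicit unassigned column.

Cross-validation is stratified k-fold (default 5) with a fixed seed; per
fold the embedding is fitted on the training annotations only, held-out
cells are projected, clustered together with the training cells, and voted
on with training annotations alone. Accuracy is reported over held-out
cells that received an assignment, with the unassigned fraction alongside;
the confusion matrix has true classes as rows and predicted classes plus
`unassigned` as columns.

## Phagocytosis

Automatic thresholds are 256-bin histogram algorithms, foreground strictly
above the threshold. *IsoData* iterates the intermeans map
`t ← (μ_below + μ_above)/2` starting from the midpoint of the grey-level
range — the midpoint start matters: images dominated by a background mode
also admit a spurious intermeans fixed point inside the background noise,
which a mean-started iteration can fall into. *Huang* minimises the fuzzy
Shannon entropy of the memberships `u(g) = 1/(1 + |g − μ_class|/C)` over
all candidate thresholds (`C` = grey-level range). Huang suits the dim,
heavy-tailed cell channel; IsoData the punctate particle channel.

Containment uses a strict majority rule: a particle's host is the cell
overlapping more than 50% of its area; exactly half or less means no host.
The rule is deterministic and insensitive to single-pixel boundary noise.
Particles are tracked across frames by nearest-centroid linking with a
maximum step of one particle diameter (floor of 2 px). A track is a
*confirmed* engulfment when, over at least three hosted frames, (a) its
frame-to-frame displacement matches its host's within a tolerance (default
3 px/frame) and (b) its area shrinks by at least `min_shrink` (default 10%)
over the window. The third criterion human observers use — visible
phagosome pouches — is inherently visual; records carry a `needs_review`
flag instead of a fake automation of it. Raising `min_shrink` can only
shrink the confirmed set (monotone gate).

The summary statistics are literal arithmetic (README): the phagocytosis
index normalises the engulfed area fraction by the number of microglia in
the field, and ΔSYTOX is reported signed, without clamping.

## Reporting

Compositions are counts per group over the seven classes plus `unassigned`;
percentages are per-group. Two groups are compared with Pearson's
chi-squared on the count table (no continuity correction); classes empty in
both groups are pooled out before the test and named in the result, since
they would contribute zero expected counts. Multiple groups are compared
pairwise against a reference with Benjamini–Hochberg adjusted p-values —
the adjustment choice is this package's, made explicit here because
"adjusted p" alone underdetermines it.

## Synthetic data

The generator emulates the *structure* of the real assay, not its optics:
cells are rendered from parameterized archetype geometry (soma outline as a
radial function with optional elliptic stretch and boundary waves; processes
as constant-width capsules whose centrelines pass through the soma centre;
side branches attached part-way along a process), sampled at pixel centres
for reproducible sub-pixel placement; particles are disks; intensity is a
constant amplitude or a centre-weighted profile; noise is additive Gaussian
on a constant background. There is no point-spread function, no
photobleaching, no astrocyte/neuron background — passing tests therefore
establish the correctness of the *computations* (thresholding, bookkeeping,
feature formulas, voting, statistics), not robustness to real-microscopy
artefacts.

Archetype defaults are this package's construction (the source classes are
described only qualitatively): round is a 9 µm disk; inflamed ameboid its
double-area lobed cognate; fried egg a large (16 µm) mildly elliptic
pancake and inflamed fried egg its larger, wavier cognate; hypertrophic a
7 µm soma with three 25 µm processes and three skeleton junctions; inflamed
hypertrophic doubles the soma area and process length and adds two
junctions; bipolar is an elongated soma with exactly two opposite,
unbranched 30 µm processes. `branch_points` counts *total* skeleton
junctions, including the central junction that necessarily forms where
three or more process centrelines meet — the renderer adds side branches to
reach the requested count, and the rendered truth is verified by independent
re-skeletonization in the tests.

The benchmark sampler jitters continuous parameters by ±12% per cell and
exposes a `separation` dial in [0, 1]: 1 keeps the default archetypes, 0
collapses all classes' continuous geometry onto the across-class mean (and
branch counts onto their family mean), so classifier accuracy can be
studied as class overlap grows. Time-lapses move cells at constant per-cell
velocities; engulfed particles translate with their host and shrink
geometrically (area factor `1 − shrink_rate` per frame), free particles are
static.

## Problem sizes and determinism

The bundled benchmarks use sizes chosen to exercise every code path while
staying comfortable on a single CPU: 10–12 cells per segmentation field,
50 cells per class (350 total) for the classifier benchmark, 5-frame
time-lapses for engulfment. Every stochastic step (generator jitter, UMAP,
fold shuffling, permutation controls) is driven by explicit seeds; the
end-to-end pipeline writes byte-identical CSVs when rerun with the same
config and seed.

## Known limitations

* The segmentation smoother's variant and parameters of the original
  interactive tooling are not published; iterations and conductance are
  exposed in the config rather than fixed.
* The exact identity of the original seventeen measured features is defined
  by the source tooling, not the text; the set here completes the eleven
  shape symbols implied by the derived formulas with centroid and four
  intensity summaries. The classifier consumes whatever columns exist, so
  the completion is not load-bearing.
* Tracking is overlap-based and will mislink cells that jump more than
  their own size between frames.
* The synthetic benchmark's class separability is by construction;
  cross-validated accuracy on it is an upper bound, not a forecast, for
  real annotated cultures.
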