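# Methods

## Problem setting

A mitosis detector reduces a gigapixel H&E whole-slide image to a point
pattern: candidate mitotic figures with pixel coordinates and a probability.
Clinical grading, however, is defined on a *region*: the mitotic count (MC)
is the number of mitotic figures in the ~2 mm² tumor area with the highest
mitotic activity, and the Bloom–Richardson (BR) mitotic score discretizes it
(≤ 7 → 1, 8–14 → 2, ≥ 15 → 3, the College of American Pathologists cut-offs
for a 2 mm² field). This package implements the region step: candidate
filtering, hotspot selection by two different area models, case-level
aggregation, and the agreement statistics used to compare two MC readings.

All geometry is computed in millimetres after converting pixel coordinates
(origin top-left, x rightward, y downward) with the scan resolution in
µm/pixel; a single internal unit avoids mm²/px² confusion. Working at the
default 0.23 µm/pixel, 1 mm ≈ 4 348 px.

## Filtering

Candidates are kept when probability ≥ threshold and when their location
lies inside any tumor polygon. Both comparisons are **closed**: the stated
operating point itself is accepted (the detector's operating point is a
chosen point on its ROC curve, so excluding it would be arbitrary), and a
point on the tumor outline or on a selected region's boundary counts as
inside. The closed convention is applied uniformly, so the points a hull is
built through are always among the points it encloses. Filtering is
idempotent and order-independent, and both properties are tested.

## Window search

The window is the rectangle of area *A* (default 2 mm²) with width:height
ratio ρ (default 4:3), hence width √(Aρ) ≈ 1.633 mm and height √(A/ρ) ≈
1.225 mm, landscape only, axis-aligned. Candidate positions form a grid
anchored at the detections' bounding box expanded by one window dimension
per side; the stride defaults to a quarter of each dimension. The phrase "an
overlap of a quarter of the width and height" admits two readings — stride =
0.25·dimension (75 % overlap, the default here) or overlap = 0.25·dimension
(stride 0.75) — and both are available (`window_literal_overlap`); the finer
default grid never counts fewer MFs. Ties break at the smallest row-major
grid index so runs are reproducible. The exact optimum of the fixed-window
count is computable because an optimal window can always be translated until
one enclosed point lies on its left edge and one on its top edge; this
translate-set search (all (xᵢ, yⱼ) anchor pairs) is kept as the independent
test oracle. A fixed-phase grid cannot always attain it: when the optimal
point subset spans almost the full window, the feasible anchor interval is
shorter than the stride. At stride = dimension/50 this affects ~3 % of dense
random instances, each by exactly one count; the discretization is inherent
to any grid and documented rather than hidden.

## BAME convex hull

The bounded-area maximum-enclosing (BAME) convex hull is the convex polygon
with area ≤ the bound that encloses the most detections. Restricting hull
vertices to detection points loses nothing: any enclosing convex region can
be replaced by the convex hull of the points it encloses, which is no larger.
A convex polygon was preferred over fixed shapes because it conforms to the
tissue the way a pathologist's field selection does, without sweeping in
empty regions.

**Patch decomposition.** The slide is tiled with square patches of 4 mm²
(side 2 mm) overlapping by 0.5 mm; the last row/column is clamped to the
detection extent so patches never overhang and every point is covered.
Because a patch is only 2 mm wide, a hull spanning it still has room for an
average width of 0.5 mm before the 2 mm² bound is violated — an implicit
aspect-ratio bound that prevents degenerate, thinly stretched hulls — and
per-patch problem sizes keep the exact solver practical.

**Exact solver (≤ 25 points per patch).** Branch and bound over
convex-position vertex chains. Every strictly convex polygon with vertices
among the points is enumerated exactly once: its anchor is its lowest vertex
(minimal (y, x)), and the remaining vertices follow in strictly ascending
angular order around the anchor with left turns enforced. The fan
decomposition from the anchor makes the area additive over triangles, so a
chain prunes as soon as its partial area exceeds the bound; a second prune
compares the incumbent against the enclosed weight so far plus the total
weight of points still ahead in angular order (a safe upper bound, since a
future fan triangle can only contain points at angles past the current
vertex). Enclosed points are marked triangle-by-triangle during the descent;
the returned optimum is recounted with the package-wide containment
predicate so boundary decisions are uniform. Degenerate optima (collinear
configurations under tiny bounds) are covered by an O(m³) scan over single
locations and closed segments. Coincident detections are deduplicated for
vertex construction but counted with multiplicity. Optimality is tested
against brute-force subset enumeration (every subset's hull, feasibility,
enclosure count) on a thousand random instances.

**Heuristic (> 25 points per patch).** Deterministic greedy growth: seed at
the point of maximal local density (most detections within √(bound)/2 ≈
0.71 mm), then repeatedly add the unenclosed point nearest to the enclosed
set whose inclusion keeps the hull within the bound, until no feasible
addition remains. Proximity-first growth is deliberate: maximizing per-step
capture spends the area budget on early long-range triangles, and
minimizing per-step area growth chases near-collinear far points whose thin
slivers are almost free in area; both strand part of a dense cluster
outside a saturated hull, while nearest-first wraps the cluster before
reaching outward. The heuristic is feasible by construction and never
beats the exact solver (tested); on a planted two-cluster stress instance
it retains ≥ 95 % of the dense cluster.

**Slide-level dispatch.** Each patch is solved with the 25-point rule; every
patch solution is then recounted against *all* slide detections, because a
hull near a patch border may enclose points assigned to a neighbouring
overlapping patch — the recount can only increase the count and is reported
via the winning solver label. Ties across patches break by count, then
smaller hull area, then patch index.

## Scoring and agreement

Cases aggregate by maximum: over slides, and over tumors within a slide
(annotation polygons may carry `tumor_id`); ties break lexicographically.
The MC is reported as counted in the selected region (area ≤ 2 mm²),
without normalizing small hulls up to 2 mm² — the hull being smaller means
no further mitoses were nearby, not that the field was smaller.

Paired counts are compared by the product-moment correlation with the exact
two-sided p (t transform, n − 2 df, via scipy); BR scores by linearly
weighted Cohen's κ computed directly from the 3×3 confusion matrix with
w_ij = 1 − |i − j|/2. A matrix with pₑ,w = 1 (all mass in one cell) returns
κ = 1 since no disagreement was observed. No multiple-testing correction or
κ confidence interval is computed. The κ implementation is cross-checked
against scikit-learn's label-based implementation in the tests, and the
correlation against an independent streaming (Welford) implementation.

## Synthetic data

`generate_slide` emulates detector output on one slide: true MFs are a
homogeneous Poisson background (default 0.5 /mm²) plus Gaussian hotspot
clusters (Thomas-process-like; default one hotspot of 30 MFs, σ = 0.15 mm)
truncated to the tumor polygon — Gaussian rather than uniform-disc clusters
because tissue hotspots are diffuse and fuzzy edges stress the hull
selector's boundary decisions. False positives are Poisson inside
(2 /mm²) and outside (1 /mm²) the tumor, the outside band emulating stroma
and artefacts around the outline. Scores are Beta-distributed: true ~
Beta(8, 2) (89 % of mass above the 0.64 operating point), false ~
Beta(1, 2.2) (89 % below), so the probability filter is exercised with
realistic losses in both directions. The default tumor outline is an
octagon of ≈ 71 mm²; the whole stream is a pure function of the seed.

The generator's ground truth includes `planted_mc`: the number of true MFs
inside the default 2 mm² window centred on the planted hotspot. This — not
the nominal cluster size — is the reference for recovery experiments, since
background MFs that fall beside the cluster are genuinely part of the
hotspot's 2 mm² count, and an enclosure-maximizing selector is right to
count them. Recovery experiments feed the selectors the slide's true MFs:
they measure hotspot localization, not detector calibration (by
construction of the score model, the 0.64 threshold removes ~11 % of true
candidates — a detector property the selector cannot compensate).

What the generator does **not** emulate: spatial correlation of false
positives with tissue structures, scanner-to-scanner domain shift, mitoses
on slide-edge artefacts, annotation error in the tumor outline, or any
image content. Passing the recovery suite therefore shows the selectors
find and count planted clusters correctly under realistic point-pattern
statistics — it does not validate the upstream detector.

`generate_paired_cohort` draws a latent bivariate normal with correlation ρ
and maps both margins through the Gaussian CDF and a negative-binomial
quantile function (n = 3, p = 3/11: mean 8, right-skewed like clinical MC
distributions); ρ = 1 yields identical columns and hence Pearson r = 1
exactly, used as a self-consistency check.

## Numerical conventions

- Collinearity/containment tolerance: signed-area epsilon 1e-12 mm²;
  area-bound feasibility tolerance 1e-9 mm².
- Hulls are returned counterclockwise with no three consecutive collinear
  vertices; 1–2 vertex degenerate hulls have area 0.
- Containment in arbitrary (possibly concave) tumor polygons goes through
  shapely's closed `covers`; convex-hull counting uses vectorized half-plane
  tests with the epsilon above.
- Empty inputs: the window selector returns an origin-anchored window with
  MC 0; the hull selector a degenerate single-vertex region with MC 0.
- Every tie-break (grid cells, patches, case aggregation) is total, so
  re-runs are bit-identical for a fixed seed and configuration.

## Problem sizes

The test suite validates the exact solver on 1 000 random instances of up
to 12 points (where brute-force enumeration is exact and fast), window
search on 500 instances of up to 40 points in a 5×5 mm field, and recovery
on 200 seeded synthetic slides; the acceptance script re-runs scaled
versions (200 instances, 100 slides, a 40-slide pipeline cohort) chosen to
keep a full from-scratch reproduction under a minute. The exact solver is
routinely fast at its 25-point dispatch limit (worst observed ~0.4 s at a
tight bound); its branch-and-bound worst case grows exponentially, which is
precisely why the patch dispatch hands larger patches to the heuristic.

## Known limitations

- The heuristic has no approximation guarantee; its quality is established
  empirically (dominance and planted-cluster tests).
- A hotspot straddling a patch border is only partially visible to each
  patch; the 0.5 mm overlap and the all-points recount mitigate but do not
  eliminate the effect.
- The window grid can undercount the true window optimum by one on ~3 % of
  dense instances at stride = dimension/50 (see above); the default
  clinical stride (quarter window) is coarser and inherits the same bound.
- Multi-tumor handling requires `tumor_id` properties in the annotation;
  without them a slide is treated as one tumor.
- The detector's secondary ("negative"-label review) threshold is accepted
  as configuration but no numeric default is published for it.
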