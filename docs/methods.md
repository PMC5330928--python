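# Methods

`shellprint` segments the periodic growth pattern on scallop shell images
— bright (or, on CT, dark) radial ribs crossed by concentric growth rings
— and turns the crossings of that network into minutiae-like *cyclic
structures* that can be matched between images for individual
re-identification, registration, growth measurement, and species-level
shape analysis. This note records the models, the parameters that matter,
and the design choices taken where the design was genuinely open.

## Coordinate and angle conventions

Positions are `(row, col)`, 0-based, origin at the top-left. Angles are
degrees measured counter-clockwise from the +col axis, so the direction
vector of angle φ is `(sin φ, cos φ)` in (row, col) components. All
lengths are pixels; an optional mm-per-pixel scalar can be applied by the
caller to anatomical outputs.

## Matched filtering with Gaussian kernels (enhancement)

Lines of a characteristic width respond maximally to a kernel whose
cross-line profile is the Gaussian

    ker(x) = -exp( -(x / a)^2 / (2 σ^2) ),

swept along the line direction over a finite support and shifted to zero
mean so flat regions respond exactly 0. The response image takes, per
pixel, the maximum of the convolution over a set of kernel rotations and
records the maximizing angle.

Parameters:

* `a` (dilation, default 8) and `sigma_kernel` (σ, default 2 px). Only
  their product matters for the profile width; the effective cross-line
  scale is `a·σ`. A filter matched to lines of width w wants `a·σ ≈ w/2`;
  the phantom studies (line width 3 px) therefore use σ = 0.25 with a = 8.
* `theta_set`: 17 orientations, 10°–170° in 10° steps, by default.
* `polarity`: `"dark"` enhances dark-on-bright lines (the CT convention,
  the default); `"bright"` negates the kernel for bright-on-dark camera
  images and phantoms.
* support: half-extent `ceil(3·a·σ)` across the profile and, by default,
  the same along the line; the along-line extent is a free parameter.

The translation parameter `b` exists in the kernel formula but is
absorbed by the convolution, so kernels are built centered (b = 0).
Normalization is a global z-score, `f = (M − μ)/σ_M`, with the
*population* standard deviation; the output is invariant to affine
rescaling of the input intensities.

## Hierarchical total-variation decomposition (multiscale)

The normalized response f is split by the Rudin–Osher–Fatemi model

    J(g, λ) = λ‖v‖²_L2 + TV(u),  g = u + v,

with isotropic discrete TV, iterated on the residual with a dyadic
schedule λ_k = λ_0·2^k (λ_0 = 0.01, K = 5 by default, giving u_0..u_5).
The reconstruction identity f = Σ u_k + v_K holds exactly by
construction because each residual is formed as a literal difference.

The minimizer is computed by Chambolle's dual projection iteration
(step 0.248, relative-change tolerance 1e-4, max 500 iterations). The
coarsest levels (large data weight 1/(2λ) at λ = 0.01) legitimately hit
the iteration cap; the level then carries a non-converged flag and a
slightly smoothed u_0, which does not affect the telescoping identity
and has no visible effect on the fine-scale line maps.

Binarization thresholds each component u_k at 0 (the matched-filter
response is signed); coarse components absorb broad plateaus — e.g. the
solid sector where ribs converge near the umbo — so the fine components
isolate clean line detail. Thresholding the cumulative approximation
u_0+...+u_k is available behind a flag but floods dense regions.
Post-processing removes 8-connected components below `min_pixels`
(default 20) and closes 1-px line holes with a Euclidean disk of radius
1 (the disk includes the diagonal neighbors, otherwise a 1-px gap in a
thin line never closes).

## Skeleton graph

Binary line maps are thinned to 1-px centerlines (topology-preserving
morphological thinning). Skeleton pixels with ≥ 3 skeleton neighbors in
their 8-neighborhood are junction candidates; 8-connected clusters of
them collapse to their center of mass (one junction can smear over a few
pixels after thinning). Centerline segments between clusters become
edges carrying their ordered pixel path and arc length (unit steps, √2
for diagonals). Dangling segments shorter than `min_spur` (5 px) are
discarded as thinning artifacts; longer ones end in degree-1 endpoint
nodes. Iterative deletion of degree-1 vertices leaves the unique 2-core
— the subgraph on which every cycle lives. Node kinds are assigned by
degree: 3 → bifurcation, ≥ 4 → crossover.

Outgoing edge directions at a node are measured at a fixed *fraction*
(0.3) of the edge's arc length along its pixel path. A fraction, not a
fixed pixel offset, keeps branch angles exactly invariant under uniform
rescaling of the coordinates, which the descriptor below relies on.

## Cyclic structures (SDFS, descriptor, matching)

**Extraction.** The space-based depth-first search walks directed edges
of the 2-core: arriving at a feature point, it continues along the
incident edge whose direction makes the tightest strictly-positive CCW
turn from the reversed incoming direction (the turn sense of each
candidate is the sign of the 2-D cross product of the incoming and
outgoing edge vectors; ties break toward the shorter edge). Because the
successor rule is a bijection on directed edges, its orbits partition
them — this is face tracing in the rotation system induced by the node
coordinates. Orbits with repeated nodes (bridges, dumbbell boundaries)
are dropped; of the two orientations of each face only the
negative-shoelace-area orbit is kept, which removes each component's
outer boundary without any length heuristic; faces of 3–6 points are the
cyclic structures. On planar graphs the interior faces form a minimum
cycle basis, which is the independent oracle used in the tests
(`min_cycle_basis_oracle`, exact, test-only). Note the basis is not
unique: on K4 the faces are a different — equally minimal — basis than
the oracle's, so equivalence is checked as equal cycle count (= circuit
rank), equal length multiset, and GF(2) independence.

**Descriptor.** An n-point structure maps to a 6n-vector
(n = 3,4,5,6 → 18, 24, 30, 36 dimensions):

* n cycle-edge arc lengths, normalized by their sum (scale invariance);
* 4n branch angles: at each point, the consecutive angular gaps between
  its incident edge directions (up to four per point — a bifurcation has
  three, a crossover four; points with more incident edges keep the two
  cycle edges plus the longest branches), starting at the outgoing cycle
  edge; absent slots are 0; each gap divided by 360°;
* n corner angles between consecutive cycle edges, divided by 360°.

The cycle is first re-oriented to positive signed area, and the starting
point is the rotation giving the lexicographically smallest vector, so
the descriptor is independent of traversal order and of global rotation.
A structure and its mirror image are distinct (orientation is fixed);
reversal duplicates are merged at extraction time.

**Matching.** s_ij is the Euclidean (optionally city-block) distance
between descriptors of equal-size structures; `ms = min s_ij` over all
comparable pairs. When two images share no equal-size structures the
result is flagged invalid rather than given a sentinel value.

## Registration and the overlap ratio

Matched structures propose point correspondences. Because the rib/ring
lattice is locally self-similar, the single best descriptor match is not
trusted: each of the 20 best pairs proposes an affine from its own node
correspondence (proposals whose singular values leave [0.67, 1.5] are
discarded as non-physical), proposals are scored by how many structure
centroids land within 3 px of a counterpart, and the winner is refined
by two nearest-neighbor least-squares passes over all structure feature
points with a shrinking gate (a light ICP step). Linear (similarity) and
quadratic polynomial models sit behind the same interface; affine is the
default and is what the pairwise workflow uses.

The overlap ratio `ra` is the fraction of the warped query skeleton's
pixels that land within `tol` (default 1 px — the shift actually
observed between repeated captures) of a template skeleton pixel,
implemented by dilating the template with a disk of radius tol. The
reference set is the warped query skeleton; a symmetric variant (mean of
both directions) is available behind a flag.

## Anatomy: ribs, rings, growth rate

Ribs: the 180° direction range is split into six 30° sectors; a Hough
transform restricted to each sector's angles keeps up to 4 peaks above
half the *global* maximum vote (per-sector thresholds would promote
noise in rib-free sectors). The umbo is the least-squares intersection
of the detected lines, with iterative trimming of non-converging lines
(ring arcs occasionally yield straight chords) and a final refit on the
lines passing within 4 px of the intersection.

Rings: pixels within 2 px of a detected rib line are excluded; the
remaining mask pixels are binned by radius from the umbo (1-px bins,
normalized by the *available* annulus area — inside the image, outside
the rib strips — with annuli under 8 available pixels zeroed), smoothed
over 3 bins, and peak-picked greedily with neighborhood suppression
(default suppression radius: half the median peak spacing of a first
pass). Accepted radii are refined to the occupancy-weighted centroid of
the peak neighborhood, giving sub-bin accuracy (≤ 1 px on phantoms).

Growth increments are the along-rib distances between a rib line's
intersections with consecutive rings (exact line-circle intersection,
consistently on the outward side); per-rib interval lists and across-rib
means are reported, with missed intersections skipped and flagged.

## Recognition

A query/template pair yields the feature pair {ms, ra}. Training
features come from same-individual (C1) and different-individual (C2)
template comparisons; a 2-input / 10-hidden / 2-output fully connected
network with sigmoid activations is trained by full-batch gradient
descent on the squared error against [1 0] / [0 1] targets, stopping
when the mean absolute output error drops below 0.01 or at 500
iterations, restarted 10 times from random initializations keeping the
lowest-error run. Inputs are z-scored with training statistics (the two
features have incomparable units). Learning rate 0.8 and N(0, 0.5)
weight initialization are era-typical back-propagation settings.
Invalid feature pairs are excluded from training; at test time a pair
with invalid features is classified "different" (a query that shares no
structure with a template cannot be verified as the same individual).

## Synthetic phantoms (what they emulate, and what not)

A phantom is the exact geometry of the pattern: rays from a configurable
umbo across a rib fan, concentric arcs at configurable radii, rasterized
at a given line width (anti-aliasing off by default so the binary ground
truth is unambiguous), over a flat or linearly shaded background with
additive Gaussian noise. Ground truth (ray angles, ring radii, crossing
coordinates, per-pixel masks) travels with every image, so recall and
localization are computable exactly.

Default study conditions: 160×160 px canvas, umbo at (10, 10), 8 ribs
spanning 80° from 6°, 6 rings from radius 48 at spacing 18, line width
3 px, foreground 1.0 over background 0.1. The inner radius and rib
spacing are chosen so neighboring crossings stay farther apart than the
matched-filter support; closer to the umbo the rays merge into a solid
sector in any case, which no line detector can resolve.

Individuals are distinguished by per-individual jitter (σ = 3 in the
experiments): i.i.d. Gaussian perturbation of rib angles (degrees) and a
cumulative random walk on ring spacings (pixels) — growth-increment
variation is what distinguishes real individuals. Repeated captures of
one individual share the jitter realization and differ by a similarity
transform (rotation ±5°, translation ±3 px, scale ±3%), illumination
(±10%) and sensor noise (σ = 0.03); the transform is applied to the
geometry before rasterization, so the true transform is known exactly.

What the phantoms do *not* emulate: shell texture and specularities,
elliptical or warped rings, rib curvature, occlusions, and non-uniform
blur. Passing the synthetic studies therefore demonstrates the
correctness and internal consistency of the pipeline under its stated
assumptions, not camera-grade robustness.

Desk-scale experiment sizes (chosen as the package's defaults): the
recognition study uses 10 individuals × 4 images with a 50/50
train/test split, template = first training image, evaluated over every
(held-out image, template) pair at decomposition scales k = 3, 4, 5; the
species study uses 3 synthetic species × 20 specimens.

## Morphometrics

Specimens are digitized as 5 fixed landmarks, 15 ventral-edge
semilandmarks and 100 surface semilandmarks. Surface correspondence:
the template's surface points are thin-plate-spline warped into each
target using the fixed+edge landmarks (TPS via an exact polyharmonic
interpolant with degree-1 polynomial part, so affinely related landmark
sets reproduce the affine map with zero bending energy), then snapped to
the target's nearest cyclic-structure centroid. Semilandmarks are
snapped, **not** slid — no tangent-direction relaxation is performed.
Generalized Procrustes superimposition centers, scales to unit centroid
size, and rotates to the iteratively re-estimated consensus (proper
rotations only, convergence 1e-8). PCA runs on the covariance of the
flattened Procrustes coordinates; species difference is the Euclidean
distance between group mean shapes; species sorting is scored as linear
discriminant accuracy in the PC1–PC2 plane. For phantoms, landmarks come
from ground-truth geometry (umbo, rib-fan extremes, outer-ring arc,
ray-ring crossings).

## Numerical choices and degenerate inputs

* Constant images: the response normalizer raises on zero variance.
* ROF: non-convergence returns the best iterate with a warning flag.
* SDFS ties (two candidates at the same turn angle): shorter edge wins.
* Cycles with more than 4 incident edges at a node keep the 4 longest.
* Affine estimation refuses < 3 or collinear correspondences; the
  feature extractor flags the pair invalid instead of failing.
* The descriptor's lexicographic canonicalization rounds to 9 decimals
  before comparison so float noise cannot flip the starting rotation
  between two runs of the same data.

## Known limitations

* SDFS assumes an approximately planar embedding; raster graphs with
  crossing-free geometry satisfy this, but a heavily corrupted skeleton
  can yield orbits that are neither simple nor face-like (they are
  filtered, costing recall, never precision).
* Rings are modeled as circles about the umbo; strong eccentricity
  spreads radial-profile peaks (3-bin smoothing tolerates mild cases).
* The overlap ratio is asymmetric by construction.
* Recognition features are 2-D by design; populations with near-twin
  individuals would need richer features than {ms, ra}.
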