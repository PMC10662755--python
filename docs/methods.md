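# Methods

This note records the models, parameter choices and numerical conventions
behind `isletrings`, including the places where the design was genuinely
open and what the synthetic-data generators do and do not emulate.

## Data model

An islet is a list of cells, each with 2D or 3D Euclidean coordinates in
input units (µm or pixels; no unit conversion is ever applied, and all
thresholds below are in those units) and a type in {beta, alpha, delta}.
Alpha and delta cells are pooled into one *alphadelta* class; the analysis
always contrasts a *structure* class (forming the ring) against a *marker*
class (enclosed).  Cell ids are 0-based row order within an islet and all
outputs reference ids, never coordinates.  Islets with fewer than five
cells of either class are excluded from analysis.  Exactly duplicated
coordinates are allowed but flagged with a warning; downstream geometry
treats them as distance-0 pairs.

## Class graphs

**Pair distribution function.**  g(r) is the observed number of unordered
pairs per radial shell of width 0.5 divided by the count expected for
uniform placement in the islet's axis-aligned bounding box:
n(n−1)/2 · annulus(r, w)/box.  The normalizing box measure uses the product
of the *positive* coordinate extents so collinear sections remain usable;
only a fully coincident point set is rejected.  r_max defaults to the
bounding-box diagonal, so every pair is binned.  Edge corrections are
deliberately omitted: the normalization only has to be monotone and
deterministic for the peak geometry to be meaningful.

**Peak finding.**  Peaks are interior shells with g[k−1] < g[k] ≥ g[k+1]
(plateaus collapse to their first shell), denoised in two ways chosen after
inspecting g(r) on jittered lattices: maxima below 0.2× the global maximum
are dropped (shot-noise bumps in the tails), and adjacent maxima whose
separating valley stays above 0.5× the smaller maximum are merged into the
taller one (a single physical peak split by noise).  Both ratios are
exposed as parameters; the raw scan is recovered with
`valley_ratio=1, min_height_ratio=0`.

**Neighborhood radius τ.**  τ is the shell-center radius of the minimum of
g strictly between the second and third peaks (smallest radius on ties).
With fewer than three peaks the fallback is the first local minimum after
the first peak — the "just past the primary correlation" intent — and with
no peaks at all a `TauEstimationError` demands a user-supplied τ.  On
square lattices (spacing 10, jitter σ = 0.5) the estimate falls strictly
between the second shell 10√2 and the third shell 20 in ≥ 96% of seeds.

**Edges and shadow rule.**  Edges join same-class cells at distance ≤ τ
(inclusive).  An edge {u, v} is removed when any third cell projects
strictly between u and v with perpendicular distance < `cell_radius`
(default 1.0 input unit).  The obstruction geometry is a corridor rule of
our own design (the source method is cited but not specified in the
original literature); whether obstructors are restricted to the same class
is likewise unstated, so all islet cells obstruct by default with a
`same_class_only` flag.

## Geometric cycles

The structure graph is planarized: every properly crossing edge pair is
subdivided at the intersection by a degree-4 dummy vertex, repeated until
crossing-free.  Collinear overlaps and endpoint touches are not treated as
crossings (measure-zero for jittered data).  Each planar edge remembers the
original cell-cell edge it descends from.

The cycle basis is taken off a *minimum* spanning tree (Euclidean weights,
lexicographic id tie-breaks) — the tree choice is genuinely open and can in
principle affect the enclosure classification; minimum-weight was fixed for
determinism.  Marker cells are grouped by the exact set of basis cycles
containing them (winding number; a marker exactly on a cycle edge counts as
*not* enclosed — a cell on the ring is mantle, not core).

For each enclosure class S, candidate anchor pairs (marker, structure
vertex) are tried in order of distance (ties by id pair).  The walk starts
at the neighbor of v\* whose angle is the smallest angle greater than
θ\* = angle(marker, v\*) and continues by the minimal counterclockwise
turn: the neighbor whose angle from the current vertex is the smallest
angle strictly greater than the angle of the previous vertex, wrapping to
the smallest angle when none is greater.  This traces one face of the
planar subdivision per starting edge.  When chords subdivide the enclosing
region into several faces, no face contains all of S, so before a pair is
marked incompatible the *mirror start* is tried — the first neighbor
rotating clockwise from θ\*, same continuation — which starts the trace
onto the face on the other side and recovers the outer ring.  A walk
exceeding 2|E| steps is treated exactly like a geometric failure.  A cycle
is accepted only if every member of S has nonzero winding number; if all
pairs fail, the class has no cycle (a distinguishable outcome, not an
error).  Each accepted cycle also records its *support*: the real cells
whose edges make up the walk (segments through dummy vertices contribute
their source edge's endpoints).  Comparisons and distances are always
computed on the support, since distances are defined between cells.
β-cycles around αδ-components use the same machinery with the roles
swapped.  Partial (non-closed) loops are out of scope.

## Persistent homology

Simplices are totally ordered: edges by length (ties by id pair), triangles
by the position of their largest-order boundary edge (ties by the remaining
edge positions), tetrahedra by their diameter — the longest edge among
their faces — with the same deterministic tie-breaks.  Boundary matrices
over GF(2) are stored as integer bit columns; the standard column reduction
adds the earlier of two pivot-sharing columns into the later one and logs
every addition in V.  The module-level `VALIDATE` flag re-checks
R = D·V, unit upper-triangular V and pivot uniqueness after every
reduction; the test suite enables it globally.

Two 2D modes exist.  *Max-persistence* uses the full clique filtration on
one class's cells (all pairwise edges, all triangles) and reports the
largest finite dimension-1 persistence — a scalar per islet and class.
*Significant-cycle* mode restricts edges to the τ-and-shadow graph and
excludes triangles containing any marker cell (horizontal-ray test,
boundary inclusive), so features wrapping markers never die; for each empty
column i of R<sub>e</sub> whose index is no pivot row of R<sub>t</sub>,
column i of V<sub>e</sub> is the representative edge set.  A representative
is necessarily a GF(2) cycle (checked; violation raises).  Marker enclosure
for an arbitrary edge set uses even-odd ray-crossing parity against the
whole set, which equals the winding parity over its simple-loop
decomposition and is well defined for unions of loops.  Representatives
enclosing no marker are discarded.

In 3D, edges use a fixed threshold (default 25, the units of the source
volumes; exposed as a parameter) instead of a τ estimate; tetrahedra whose
closure contains a marker (barycentric test, boundary inclusive) are the
forbidden fills.  Triangles that contain a marker exactly in their plane
are excluded as well: for generic coordinates this is a measure-zero event
and therefore vacuous, but for exactly symmetric shells (an octahedron with
the marker at the centroid — the canonical worked fixture) the in-plane
fill triangles would otherwise keep spurious flat 2-cycles alive.  Undying
dimension-2 features are read from V<sub>t</sub> as closed triangulated
surfaces (closure checked); marker enclosure uses ray-casting parity with a
fixed irrational ray direction and deterministic fallback directions when a
crossing grazes a triangle border.

## Cycle refinement and comparison

Representatives are not unique and can detour, so two shorteners tighten
them under a hard contract, asserted everywhere: the edge count never
increases and the enclosed marker set never changes.

*Greedy*: repeatedly replace a subpath of a boundary loop by a strictly
shorter (fewer-edge) graph path when the result is still a closed GF(2)
cycle with the same enclosed set; terminates because the edge count
strictly decreases.  This subpath-replacement scheme is a simplified
stand-in satisfying the published contract of the shortening it emulates.

*Stochastic*: for each disk radius in [0.1, 0.2, …, 1.0] (about a tenth of
the smallest neighborhood radius seen in practice) and each of 50
perturbations, structure cells are displaced uniformly in disks (the
perturbation distribution was open; uniform-in-disk was fixed), edge
lengths are rounded to the nearest integer (a `rounding_scale` parameter
covers sub-unit coordinate systems), tie orders among equal rounded lengths
are resampled up to 50 times, and the significant-cycle computation is
re-run — up to 25 000 representative sets.  Per enclosed marker set the
fewest-edge boundary wins (deterministic tie-break by edge list), reported
on the unperturbed coordinates.  One RNG stream per (radius, perturbation)
derives from the master seed, so results are bit-reproducible.  Pipeline
runs default to greedy only; stochastic shortening is opt-in because its
cost is the product of all three loop counts.

Cycles *match* on equal enclosed sets; the distance is the symmetric
Hausdorff distance between the cell coordinate sets (dummy vertices
stripped); *proximal* = matched and distance ≤ τ of the structure class.

## Morphometry

The islet outline is an alpha shape built directly on the Delaunay
triangulation: triangles with circumradius < 1/shrink_factor are kept and
unioned (shrink factor 0 ⇒ convex hull).  The initial shrink factor is
1/max(τ_β, τ_αδ) — the inverse of the larger neighborhood radius, our
reading of an ambiguous symbol in the source description — and halves until
the shape is a single polygon, necessarily terminating at the hull.  The
islet center is the centroid of the periphery polygon.  Cycle-to-periphery
and center-to-cycle distances are boundary-to-boundary (shapely
`LineString.distance`), so a cycle nested inside the islet still gets a
positive distance; the "estimated area" of an islet is the alpha-shape
polygon area (shoelace), kept separate from the bounding-box area used to
normalize g(r).  No 3D periphery is estimated.

## Statistics

Islets are characterized by β-fraction n_β/(n_β+n_α+n_δ) and ln(1 + total
cells).  KDEs use scipy's Gaussian kernel with Scott's-rule bandwidth
(recorded in the output) on a 100×100 grid whose ranges are the min/max
over the union of compared samples expanded by 5%, shared across groups so
KL is well defined.  For KL, grids are floored at machine-epsilon-scaled
mass and normalized to sum 1; KL(P,P) = 0 exactly and KL ≥ 0 by the Gibbs
inequality.  The 2D two-sample KS test is the Fasano–Franceschini quadrant
statistic (max quadrant-probability difference swept over the points of
both samples, averaged between sweeps) with the standard asymptotic
Kolmogorov p-value including the correlation correction; below 10 points a
warning flags the p-value as unreliable.  1D persistence distributions use
the two-sided Mann-Whitney U test (tie-corrected asymptotic normal).  The
cohort summary reports, per group, the percentage of islets with at least
one non-singular (size > 1) marker component *fully* inside one cycle
(every member cell enclosed by that same cycle), the median and 95th
percentile of maximum dimension-1 persistence per class, KDE peaks and α/δ
count summaries; and per group pair, both KL directions, the 2D KS test and
Mann-Whitney results.

## Synthetic data

The imaging-derived tables the method was designed for are not
redistributable, so seeded generators emulate their salient geometry at the
same coordinate scale (spacings ~10–20 units, matching neighborhood radii
of order 10 and the 3D threshold 25): mantle rings (markers uniform in a
core disk, structure cells equally spaced on a circle with Gaussian
jitter, default 0.2), intermixed islets (uniform positions, i.i.d. types
with a set β-fraction), square/hex lattices with analytic shell radii as
ground truth, 3D polyhedral shells, and mixed cohorts with varying sizes
(rings: 6–12 mantle cells at radius 8–15 around 3–6 core cells plus a few
outside cells; intermixed: 15–50 cells at ~0.01 cells per square unit).
The α:δ split within the pooled class defaults to 2:1.  What these fixtures
do *not* emulate: segmentation noise, missed or mislabelled cells, tissue-
section cropping, anisotropic densities and partial rings.  Passing tests
therefore demonstrate algorithmic correctness and internal consistency of
the two methods, not field performance on imaging data.

## Problem sizes and verification

The suite verifies the persistence computation against an independent
oracle that derives the pairing purely from GF(2) ranks of boundary
submatrices (100 random clouds of ≤ 12 points), winding against even-odd
ray casting (10⁴ cases), and the shadow/threshold/Hausdorff/Mann-Whitney
operations against brute-force enumeration.  Concordance between the two
ring detectors is measured on 200 synthetic ring islets (jitter 5% of the
ring radius) and the cohort workflow on 100 ring + 100 intermixed islets;
at these sizes the whole suite runs in well under a minute on one core.
Known limitations: τ estimation needs enough cells for a usable g(r) (tiny
islets fall back or require a manual τ); planarization handles proper
crossings only; the geometric walk is 2D by construction; and stochastic
shortening at its full default budget is orders of magnitude slower than
the greedy pass that the pipeline applies by default.
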