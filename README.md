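# isletrings

Geometric and topological detection of cell-type ring structures in islets
of Langerhans.

## The problem

Pancreatic islets contain β-cells (insulin), α-cells (glucagon) and δ-cells
(somatostatin).  Imaging pipelines reduce an islet section or volume to a
table of nucleus coordinates with a cell-type label per cell.  A recurring
cytoarchitectural motif is a *ring* (mantle) of one cell class around a
*core* of the other — e.g. αδ-cells wrapping a connected clump of β-cells —
and the prevalence of such rings differs across developmental stages and
between control and diabetic tissue.  `isletrings` quantifies these rings
with two independent methods and provides the morphometric and statistical
layer to compare cohorts.  It is a library for Python users (imaging /
computational-biology analysts), with an `examples/` directory of short
scripts and a thin `isletrings` CLI for batch runs.

## The methods

Both methods operate on per-class spatial graphs G<sub>β</sub>, G<sub>αδ</sub>:
the neighborhood radius τ of a class is estimated from its pair
distribution function g(r) (radial shells of width 0.5; τ = the minimum of
g between its second and third peaks), cells at most τ apart are joined,
and edges obstructed by an intervening cell are removed (shadow rule).

1. **Geometric cycles.**  The class graph is planarized with dummy vertices
   at edge crossings.  A cycle basis is read off a minimum spanning tree;
   marker cells are grouped by which basis cycles contain them (winding
   number).  For each group S, a closed walk P<sub>S</sub> =
   [v\*, v₁, …, vₙ, v\*] is traced by taking, at every vertex, the minimal
   counterclockwise turn — the neighbor whose angle is the smallest angle
   exceeding the arrival reference angle — and verified to enclose all of S.

2. **PH cycles.**  Dimension-1 persistent homology is computed by the
   standard GF(2) column reduction of the boundary matrices D<sub>e</sub>
   (vertices × edges, ordered by length) and D<sub>t</sub> (edges ×
   triangles, ordered by the largest-order boundary edge).  A pivot (i, j)
   of the reduced R<sub>t</sub> pairs a feature born at |e<sub>i</sub>| with
   its death at the scale of t<sub>j</sub>.  Fill triangles containing a
   marker cell are excluded from the filtration, so holes around markers
   never die; their representatives (columns of the operation log
   V<sub>e</sub>) are the PH cycles, tightened by greedy and stochastic
   shortening.  In 3D the same construction one dimension up (tetrahedra as
   forbidden fills) yields closed triangulated surfaces around marker cells.

A geometric cycle L and a PH cycle L̂ *match* when they enclose the same
marker set and are *proximal* when additionally the Hausdorff distance
d(L, L̂) ≤ τ.

## Worked example

```sh
python examples/01_detect_rings.py
```

prints, for a synthetic islet of 8 mantle (αδ) cells around 3 core (β)
cells:

```
estimated neighborhood radius tau = 15.25 (input units)
alphadelta graph: 8 cells, 16 edges
cycle walk (vertex ids): [13, 12, 18, 16, 17, 14, 15, 11, 13]
  encloses beta cells:   [0, 1, 2]
  real-cell support:     [3, 4, 5, 6, 7, 8, 9, 10]
```

τ ≈ 15 admits second-neighbor chords, so the planarized graph contains
dummy vertices (ids ≥ 11); the walk is the inner face enclosing all three
β-cells, and its real-cell support is the full 8-cell mantle.  Running
`python examples/03_compare_methods.py` shows that on 25 such islets every
geometric cycle has a proximal PH cycle — the two independent methods
agree.  See `examples/` for persistence, morphometry, cohort statistics and
3D voids.

Input tables are CSVs with columns `islet_id,x,y[,z],cell_type`; only
islets with at least five β- and five αδ-cells are analysed.  The same
workflow is scriptable:

```sh
isletrings simulate --kind cohort --n 50 --seed 1 --out cells.csv
isletrings compare cells.csv
isletrings morphometry cells.csv --out results.json
isletrings stats results.json --out report.json
```

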