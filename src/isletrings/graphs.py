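"""Per-cell-class spatial graphs.

For each cell class the neighborhood radius tau is estimated from the pair
distribution function g(r) (the observed-to-expected ratio of pair counts in
radial shells), edges connect cells at most tau apart, and edges obstructed
by a third intervening cell are pruned by a shadow rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .datamodel import DegenerateInputError, IsletSection


class TauEstimationError(RuntimeError):
    """The pair distribution curve has no peaks; tau must be supplied."""


@dataclass
class PairDistributionCurve:
    """g(r) over radial shells of constant width.

    ``shell_edges`` has length K+1; shell k covers [edges[k], edges[k+1]).
    """

    shell_edges: np.ndarray
    g_values: np.ndarray
    peaks: list[float] = field(default_factory=list)

    @property
    def shell_width(self) -> float:
        return float(self.shell_edges[1] - self.shell_edges[0])

    @property
    def shell_centers(self) -> np.ndarray:
        return 0.5 * (self.shell_edges[:-1] + self.shell_edges[1:])


@dataclass
class CellTypeGraph:
    """Threshold-and-shadow graph on the cells of one class."""

    cell_class: str
    ids: list[int]
    coords: dict[int, np.ndarray]
    edges: set[tuple[int, int]]
    tau: float

    def edge_length(self, e: tuple[int, int]) -> float:
        return float(np.linalg.norm(self.coords[e[0]] - self.coords[e[1]]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        for u, v in self.edges:
            g.add_edge(u, v, weight=self.edge_length((u, v)))
        return g


def bounding_box_area(coords: np.ndarray) -> float:
    """Product of the coordinate extents: area of the axis-aligned bounding
    box in 2D, volume in 3D.  A single cell gives 0."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 1:
        raise DegenerateInputError("need at least one cell")
    extent = coords.max(axis=0) - coords.min(axis=0)
    return float(np.prod(extent))


def _annulus_measure(r_lo: np.ndarray, r_hi: np.ndarray, dim: int) -> np.ndarray:
    if dim == 2:
        return np.pi * (r_hi**2 - r_lo**2)
    if dim == 3:
        return 4.0 / 3.0 * np.pi * (r_hi**3 - r_lo**3)
    raise ValueError("dim must be 2 or 3")


def pair_distribution(
    coords: np.ndarray,
    shell_width: float = 0.5,
    r_max: float | None = None,
) -> PairDistributionCurve:
    """Pair distribution function of a point set.

    g(r_k) is the number of unordered pairs at distance in [r_k, r_k + w)
    divided by the count expected for n points placed uniformly at random in
    the bounding box: n(n-1)/2 * shell_measure / box_measure.  The default
    shell width is 0.5 input units and r_max defaults to the bounding-box
    diagonal so that every pair is binned.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n, dim = coords.shape
    if n < 2:
        raise DegenerateInputError("pair distribution needs at least two cells")
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    extent = coords.max(axis=0) - coords.min(axis=0)
    # degenerate axes (e.g. collinear sections) drop out of the box measure;
    # only a fully coincident point set is rejected
    positive = extent[extent > 0]
    if positive.size == 0:
        raise DegenerateInputError("all cells coincident: zero box measure")
    box = float(np.prod(positive))
    if r_max is None:
        r_max = float(np.linalg.norm(extent))
    n_shells = int(np.ceil(r_max / shell_width))
    edges = shell_width * np.arange(n_shells + 1)
    observed, _ = np.histogram(pdist(coords), bins=edges)
    expected = n * (n - 1) / 2.0 * _annulus_measure(edges[:-1], edges[1:], dim) / box
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, observed / expected, 0.0)
    return PairDistributionCurve(shell_edges=edges, g_values=g)


def find_peaks(
    curve: PairDistributionCurve,
    valley_ratio: float = 0.5,
    min_height_ratio: float = 0.2,
) -> list[float]:
    """Peaks of g: interior local maxima (shells k with g[k-1] < g[k] >=
    g[k+1]; a plateau collapses to its first shell), denoised.

    Shot noise in the shell histogram produces two artifacts that a raw
    local-maximum scan would report as peaks: tiny bumps in the tails (any
    maximum below ``min_height_ratio`` times the global maximum of g is
    dropped) and single physical peaks split by shallow dips (two adjacent
    maxima merge when the valley between them stays above ``valley_ratio``
    times the smaller maximum; the taller shell wins, the earlier one on
    ties).  ``valley_ratio=1, min_height_ratio=0`` recovers the raw scan.
    Returns shell-center radii in increasing order and caches them on the
    curve.
    """
    centers = curve.shell_centers
    peaks = [
        float(centers[k])
        for k in _peak_indices(curve, valley_ratio, min_height_ratio)
    ]
    curve.peaks = peaks
    return peaks


def _peak_indices(
    curve: PairDistributionCurve,
    valley_ratio: float = 0.5,
    min_height_ratio: float = 0.2,
) -> list[int]:
    g = curve.g_values
    floor = min_height_ratio * (g.max() if len(g) else 0.0)
    idx = [
        k
        for k in range(1, len(g) - 1)
        if g[k - 1] < g[k] >= g[k + 1] and g[k] >= floor
    ]
    merged = True
    while merged and len(idx) > 1:
        merged = False
        for a in range(len(idx) - 1):
            p, q = idx[a], idx[a + 1]
            valley = g[p + 1 : q].min() if q > p + 1 else min(g[p], g[q])
            if valley >= valley_ratio * min(g[p], g[q]):
                keep = p if g[p] >= g[q] else q
                idx = idx[:a] + [keep] + idx[a + 2 :]
                merged = True
                break
    return idx


def neighborhood_radius(curve: PairDistributionCurve) -> float:
    """Neighborhood radius tau: the shell-center radius at the minimum of g
    strictly between the second and third peaks (smallest radius on ties).

    With fewer than three peaks the fallback is the first local minimum of g
    after the first peak (the last shell if g decays monotonically).  With no
    peaks at all a :class:`TauEstimationError` is raised and the caller must
    supply tau.
    """
    g = curve.g_values
    centers = curve.shell_centers
    kp = _peak_indices(curve)
    if not kp:
        raise TauEstimationError(
            "pair distribution curve has no peaks; supply tau manually"
        )
    if len(kp) >= 3:
        lo, hi = kp[1], kp[2]
        interior = range(lo + 1, hi)
        k_min = min(interior, key=lambda k: (g[k], k))
        return float(centers[k_min])
    # fallback: first local minimum after the first peak
    k1 = kp[0]
    for k in range(k1 + 1, len(g) - 1):
        if g[k - 1] > g[k] <= g[k + 1]:
            return float(centers[k])
    return float(centers[len(g) - 1])


def build_edges(ids: list[int], coords: np.ndarray, tau: float) -> set[tuple[int, int]]:
    """All unordered pairs of cells at Euclidean distance <= tau (inclusive)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    tree = cKDTree(coords)
    pairs = tree.query_pairs(tau)
    out = set()
    for a, b in pairs:
        u, v = ids[a], ids[b]
        out.add((min(u, v), max(u, v)))
    return out


def _obstructs(u: np.ndarray, v: np.ndarray, w: np.ndarray, radius: float) -> bool:
    d = v - u
    denom = float(d @ d)
    if denom == 0:
        return False
    t = float((w - u) @ d) / denom
    if not (0.0 < t < 1.0):
        return False
    perp = np.linalg.norm(w - (u + t * d))
    return perp < radius


def shadow_filter(
    graph: CellTypeGraph,
    islet: IsletSection,
    cell_radius: float = 1.0,
    same_class_only: bool = False,
) -> CellTypeGraph:
    """Remove edges obstructed by a third cell.

    An edge {u, v} is obstructed by cell w when w projects strictly between
    u and v on the segment and its perpendicular distance to the segment is
    below ``cell_radius``.  By default every islet cell of any type can
    obstruct; ``same_class_only`` restricts obstructors to the graph's own
    class.  Only removes edges; vertices are untouched.
    """
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    if same_class_only:
        obstructors = [
            (c.id, np.asarray(c.coords, float))
            for c in islet.cells_of_class(graph.cell_class)
        ]
    else:
        obstructors = [(c.id, np.asarray(c.coords, float)) for c in islet.cells]
    kept = set()
    for u, v in graph.edges:
        pu, pv = graph.coords[u], graph.coords[v]
        blocked = any(
            wid not in (u, v) and _obstructs(pu, pv, wc, cell_radius)
            for wid, wc in obstructors
        )
        if not blocked:
            kept.add((u, v))
    return CellTypeGraph(
        cell_class=graph.cell_class,
        ids=list(graph.ids),
        coords=dict(graph.coords),
        edges=kept,
        tau=graph.tau,
    )


def connected_components(graph: CellTypeGraph) -> list[dict]:
    """Vertex-set partition with a non-singular (NS) flag per component.

    A component is NS when it has more than one cell.
    """
    comps = nx.connected_components(graph.to_networkx())
    out = [
        {"members": frozenset(c), "ns": len(c) > 1}
        for c in sorted(comps, key=lambda c: min(c))
    ]
    return out


def build_class_graph(
    islet: IsletSection,
    cell_class: str,
    shell_width: float = 0.5,
    cell_radius: float = 1.0,
    tau_override: float | None = None,
    shadow: bool = True,
    same_class_only: bool = False,
) -> CellTypeGraph:
    """Full graph-construction pipeline for one cell class of one islet:
    pair distribution -> tau -> threshold edges -> shadow filter."""
    ids, coords = islet.class_arrays(cell_class)
    if tau_override is not None:
        tau = float(tau_override)
    else:
        curve = pair_distribution(coords, shell_width=shell_width)
        tau = neighborhood_radius(curve)
    edges = build_edges(ids, coords, tau)
    graph = CellTypeGraph(
        cell_class=cell_class,
        ids=ids,
        coords={i: coords[k] for k, i in enumerate(ids)},
        edges=edges,
        tau=tau,
    )
    if shadow:
        graph = shadow_filter(
            graph, islet, cell_radius=cell_radius, same_class_only=same_class_only
        )
    return graph
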