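"""Shortening of PH representative boundaries and geometric-vs-PH matching.

Representatives of undying features are not unique and can detour; greedy
shortening replaces subpaths by shorter graph paths, and stochastic
shortening re-runs the significant-cycle computation under small coordinate
perturbations and resampled tie orders, keeping per enclosed marker set the
boundary with the fewest edges.  Two cycles match when they enclose the same
marker set; they are proximal when they also lie within Hausdorff distance
tau of each other.
"""

from __future__ import annotations

import itertools

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .graphs import CellTypeGraph
from .homology import (
    RepresentativeBoundary,
    _edge_set_closed,
    enclosed_markers_2d,
    significant_cycles_2d,
)


@dataclass
class ShorteningConfig:
    """Stochastic-shortening parameters.

    Cells are displaced uniformly in disks of each radius in ``radii_grid``
    (default 0.1..1.0 input units, about a tenth of the smallest neighborhood
    radius seen in practice), ``n_perturbations`` times per radius; rounded
    edge lengths tie-break into at most ``max_orderings`` resampled orders.
    ``rounding_scale`` divides lengths before rounding for sub-unit
    coordinate systems (1.0 = round to nearest integer).
    """

    n_perturbations: int = 50
    max_orderings: int = 50
    radii_grid: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
    seed: int = 0
    rounding_scale: float = 1.0

    def __post_init__(self):
        if self.n_perturbations <= 0 or self.max_orderings <= 0:
            raise ValueError("counts must be positive")
        radii = list(self.radii_grid)
        if any(r <= 0 for r in radii) or radii != sorted(radii):
            raise ValueError("radii must be positive and increasing")


@dataclass
class ComparisonRecord:
    geometric_id: int
    ph_id: int
    matched: bool
    distance: float
    proximal: bool


def match(enclosed_a: frozenset[int], enclosed_b: frozenset[int]) -> bool:
    """Two cycles match when they enclose the same marker-cell set."""
    return frozenset(enclosed_a) == frozenset(enclosed_b)


def cycle_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two cell coordinate sets."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("cycle_distance requires nonempty cell sets")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def proximal(
    enclosed_a,
    coords_a,
    enclosed_b,
    coords_b,
    tau: float,
    geometric_id: int = 0,
    ph_id: int = 0,
) -> ComparisonRecord:
    """Proximal = same enclosed marker set AND Hausdorff distance <= tau."""
    m = match(enclosed_a, enclosed_b)
    d = cycle_distance(coords_a, coords_b)
    return ComparisonRecord(
        geometric_id=geometric_id,
        ph_id=ph_id,
        matched=m,
        distance=d,
        proximal=bool(m and d <= tau),
    )


def _boundary_loops(edge_set) -> list[list[int]]:
    """Decompose a GF(2) 1-cycle into closed vertex loops (every vertex has
    even degree, so an Eulerian decomposition into loops exists)."""
    adj: dict[int, list[int]] = {}
    for a, b in edge_set:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    remaining = {tuple(sorted(e)) for e in edge_set}
    loops = []
    while remaining:
        start = min(v for e in remaining for v in e)
        loop = [start]
        cur = start
        while True:
            nxt = next(
                w for w in sorted(adj[cur]) if tuple(sorted((cur, w))) in remaining
            )
            remaining.discard(tuple(sorted((cur, nxt))))
            loop.append(nxt)
            cur = nxt
            if cur == start:
                break
        loops.append(loop)
    return loops


def greedy_shorten(
    boundary: RepresentativeBoundary,
    graph: CellTypeGraph,
    marker_ids: list[int],
    marker_coords: np.ndarray,
) -> RepresentativeBoundary:
    """Replace loop subpaths by strictly shorter (fewer-edge) graph paths
    while the enclosed marker set stays identical.  Edge count never
    increases; a minimal boundary is a fixed point."""
    g = graph.to_networkx()
    edge_set = set(boundary.simplices)
    improved = True
    while improved:
        improved = False
        loops = _boundary_loops(edge_set)
        for li, loop in enumerate(loops):
            ring = loop[:-1]
            L = len(ring)
            if L < 4:
                continue
            other_loop_edges = {
                tuple(sorted(e))
                for lj, lp in enumerate(loops)
                if lj != li
                for e in zip(lp, lp[1:])
            }
            for i in range(L):
                for k in range(2, L - 1):
                    a, b = ring[i], ring[(i + k) % L]
                    try:
                        path = nx.shortest_path(g, a, b)
                    except nx.NetworkXNoPath:
                        continue
                    if len(path) - 1 >= k:
                        continue
                    kept = [ring[(i + s) % L] for s in range(k, L + 1)]
                    new_ring_edges = set(
                        tuple(sorted(e))
                        for e in itertools.chain(
                            zip(kept, kept[1:]), zip(path, path[1:])
                        )
                    )
                    if len(new_ring_edges) >= L:
                        continue
                    candidate = other_loop_edges | new_ring_edges
                    if not _edge_set_closed(candidate):
                        continue
                    enclosed = enclosed_markers_2d(
                        candidate, graph.coords, marker_ids, marker_coords
                    )
                    if enclosed != boundary.enclosed:
                        continue
                    edge_set = candidate
                    improved = True
                    break
                if improved:
                    break
            if improved:
                break
    return RepresentativeBoundary(
        simplices=frozenset(edge_set),
        enclosed=boundary.enclosed,
        birth=boundary.birth,
    )


def _tie_resampled_order(
    edges: list[tuple[int, int]],
    coords: dict[int, np.ndarray],
    rounding_scale: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Edge order by rounded length with ties shuffled."""
    keyed: dict[int, list[tuple[int, int]]] = {}
    for e in edges:
        r = int(round(np.linalg.norm(coords[e[0]] - coords[e[1]]) / rounding_scale))
        keyed.setdefault(r, []).append(tuple(sorted(e)))
    order = []
    for r in sorted(keyed):
        block = sorted(keyed[r])
        rng.shuffle(block)
        order.extend(block)
    return order


def stochastic_shorten(
    structure_graph: CellTypeGraph,
    marker_ids: list[int],
    marker_coords: np.ndarray,
    initial_boundaries: list[RepresentativeBoundary],
    config: ShorteningConfig | None = None,
) -> list[RepresentativeBoundary]:
    """Stochastic shortening of significant boundaries.

    For every disk radius and perturbation, structure cells are displaced
    uniformly in disks, edge lengths are rounded, tie orders among equal
    rounded lengths are resampled up to ``max_orderings`` times, and the
    significant-cycle computation is re-run.  Per enclosed marker set the
    boundary with the fewest edges seen in any run (including the initial
    set) wins; results are reported on the unperturbed coordinates.
    """
    config = config or ShorteningConfig()
    ids = list(structure_graph.ids)
    coords = structure_graph.coords
    edges = [tuple(sorted(e)) for e in structure_graph.edges]

    best: dict[frozenset, RepresentativeBoundary] = {}

    def offer(b: RepresentativeBoundary):
        cur = best.get(b.enclosed)
        if cur is None or b.edge_count < cur.edge_count or (
            b.edge_count == cur.edge_count
            and sorted(b.simplices) < sorted(cur.simplices)
        ):
            best[b.enclosed] = b

    for b in initial_boundaries:
        offer(b)

    marker_coords = np.atleast_2d(np.asarray(marker_coords, dtype=float))
    for ri, radius in enumerate(config.radii_grid):
        for pi in range(config.n_perturbations):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(ri, pi))
            )
            theta = rng.uniform(0, 2 * np.pi, size=len(ids))
            rad = radius * np.sqrt(rng.uniform(0, 1, size=len(ids)))
            perturbed = {
                v: coords[v] + rad[k] * np.array([np.cos(theta[k]), np.sin(theta[k])])
                for k, v in enumerate(ids)
            }
            seen_orders: set[tuple] = set()
            for _ in range(config.max_orderings):
                order = _tie_resampled_order(
                    edges, perturbed, config.rounding_scale, rng
                )
                key = tuple(order)
                if key in seen_orders:
                    continue
                seen_orders.add(key)
                boundaries = significant_cycles_2d(
                    ids,
                    perturbed,
                    set(edges),
                    marker_ids,
                    marker_coords,
                    edge_order=order,
                )
                # map back: edges are id pairs, valid on unperturbed coords
                for b in boundaries:
                    enclosed = enclosed_markers_2d(
                        b.simplices, coords, marker_ids, marker_coords
                    )
                    if enclosed:
                        offer(
                            RepresentativeBoundary(
                                simplices=b.simplices,
                                enclosed=enclosed,
                                birth=b.birth,
                            )
                        )
    return [best[k] for k in sorted(best, key=sorted)]


def compare_cycles(
    geometric_cycles,
    ph_boundaries,
    structure_coords: dict[int, np.ndarray],
    tau: float,
) -> list[ComparisonRecord]:
    """All-pairs comparison records between geometric cycles (dummy vertices
    stripped: distance is defined between cells) and PH boundaries."""
    records = []
    for gi, gc in enumerate(geometric_cycles):
        real = sorted(gc.support) or [v for v in gc.walk[:-1] if v in structure_coords]
        ga = np.asarray([structure_coords[v] for v in real])
        for pi, pb in enumerate(ph_boundaries):
            verts = sorted({v for e in pb.simplices for v in e})
            pa = np.asarray([structure_coords[v] for v in verts])
            records.append(
                proximal(gc.enclosed, ga, pb.enclosed, pa, tau, gi, pi)
            )
    return records
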