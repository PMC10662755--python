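"""Geometric ring detection.

The class graph is planarized with dummy vertices at edge crossings, a cycle
basis is read off a minimum spanning tree, marker cells are classified by
which cycles contain them (winding number), and for each enclosure class the
minimal counterclockwise-turn closed walk enclosing it is traced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import DegenerateInputError
from .graphs import CellTypeGraph


@dataclass
class PlanarGraph:
    """Straight-line graph with no interior edge crossings.

    Dummy vertices (ids above every real cell id) subdivide former crossing
    points; ``dummy_origin`` maps each dummy id to the two source edges it
    replaced.
    """

    coords: dict[int, np.ndarray]
    edges: set[tuple[int, int]]
    dummy_origin: dict[int, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=dict
    )
    #: planar edge -> the original (real-cell) edge it is a piece of
    edge_source: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    @property
    def real_ids(self) -> set[int]:
        return set(self.coords) - set(self.dummy_origin)

    def edge_length(self, e: tuple[int, int]) -> float:
        return float(np.linalg.norm(self.coords[e[0]] - self.coords[e[1]]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.coords)
        for u, v in self.edges:
            g.add_edge(u, v, weight=self.edge_length((u, v)))
        return g


@dataclass
class GeometricCycle:
    """Closed walk of structure-class vertices enclosing marker set S.

    ``walk`` starts and ends at the anchor vertex; dummy vertices may appear
    and are reported with their source-edge provenance.
    """

    walk: list[int]
    enclosed: frozenset[int]
    component_id: int = 0
    dummy_provenance: dict[int, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=dict
    )
    #: real cells whose edges form the walk (walk segments on a subdivided
    #: edge contribute the original edge's endpoints)
    support: frozenset[int] = frozenset()

    @property
    def vertex_set(self) -> frozenset[int]:
        return frozenset(self.walk)

    def polygon(self, coords: dict[int, np.ndarray]) -> np.ndarray:
        return np.asarray([coords[v] for v in self.walk], dtype=float)


def angle(v: np.ndarray, u: np.ndarray) -> float:
    """Counterclockwise angle in [0, 2*pi) of the vector v - u measured from
    the positive horizontal axis through u."""
    dx = float(v[0] - u[0])
    dy = float(v[1] - u[1])
    if dx == 0.0 and dy == 0.0:
        raise DegenerateInputError("angle undefined for coincident points")
    a = math.atan2(dy, dx)
    return a + 2 * math.pi if a < 0 else a


def _on_segment(p, a, b, tol=1e-9) -> bool:
    ab = b - a
    ap = p - a
    cross = ab[0] * ap[1] - ab[1] * ap[0]
    scale = max(1.0, float(np.linalg.norm(ab)))
    if abs(cross) > tol * scale:
        return False
    dot = float(ap @ ab)
    return -tol <= dot <= float(ab @ ab) + tol


def winding_number(point: np.ndarray, polygon: np.ndarray) -> int:
    """Signed winding number of a closed polygonal walk around a point.

    Nonzero means inside.  Points lying exactly on the polygon boundary
    report 0: a cell sitting on the ring belongs to the mantle, not the core.
    """
    point = np.asarray(point, dtype=float)
    polygon = np.asarray(polygon, dtype=float)
    if len(polygon) and not np.allclose(polygon[0], polygon[-1]):
        polygon = np.vstack([polygon, polygon[0]])
    if len(polygon) < 4:  # fewer than 3 distinct vertices: zero area
        return 0
    for k in range(len(polygon) - 1):
        if _on_segment(point, polygon[k], polygon[k + 1]):
            return 0
    wn = 0
    px, py = point
    for k in range(len(polygon) - 1):
        ax, ay = polygon[k]
        bx, by = polygon[k + 1]
        is_left = (bx - ax) * (py - ay) - (px - ax) * (by - ay)
        if ay <= py:
            if by > py and is_left > 0:
                wn += 1
        else:
            if by <= py and is_left < 0:
                wn -= 1
    return wn


def _proper_crossing(p1, p2, p3, p4) -> np.ndarray | None:
    """Interior intersection point of segments p1p2 and p3p4, or None.

    Collinear overlaps and endpoint touches are not crossings.
    """
    r = p2 - p1
    s = p4 - p3
    denom = r[0] * s[1] - r[1] * s[0]
    if denom == 0:
        return None
    q = p3 - p1
    t = (q[0] * s[1] - q[1] * s[0]) / denom
    u = (q[0] * r[1] - q[1] * r[0]) / denom
    eps = 1e-12
    if eps < t < 1 - eps and eps < u < 1 - eps:
        return p1 + t * r
    return None


def planarize(graph: CellTypeGraph) -> PlanarGraph:
    """Subdivide every pair of properly crossing edges at their intersection
    with a degree-4 dummy vertex, repeating until the drawing is crossing-free.
    The union of edge point-sets is unchanged."""
    coords = {i: np.asarray(graph.coords[i], dtype=float) for i in graph.ids}
    if coords and len(next(iter(coords.values()))) != 2:
        raise ValueError("planarization requires 2D coordinates")
    edges = {tuple(sorted(e)) for e in graph.edges}
    # provenance: each current edge descends from one original edge
    source = {e: e for e in edges}
    dummy_origin: dict[int, tuple] = {}
    next_id = max(coords, default=-1) + 1

    changed = True
    while changed:
        changed = False
        edge_list = sorted(edges)
        for i in range(len(edge_list)):
            a, b = edge_list[i]
            for j in range(i + 1, len(edge_list)):
                c, d = edge_list[j]
                if len({a, b, c, d}) < 4:
                    continue
                p = _proper_crossing(coords[a], coords[b], coords[c], coords[d])
                if p is None:
                    continue
                u = next_id
                next_id += 1
                coords[u] = p
                dummy_origin[u] = (source[(a, b)], source[(c, d)])
                edges.discard((a, b))
                edges.discard((c, d))
                for e in ((a, b), (c, d)):
                    src = source.pop(e)
                    for v in e:
                        ne = (min(v, u), max(v, u))
                        edges.add(ne)
                        source[ne] = src
                changed = True
                break
            if changed:
                break
    return PlanarGraph(
        coords=coords, edges=edges, dummy_origin=dummy_origin, edge_source=source
    )


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def minimum_spanning_forest(pg: PlanarGraph) -> set[tuple[int, int]]:
    """Kruskal MST per component under Euclidean edge weights, ties broken
    lexicographically by id pair for determinism."""
    order = sorted(pg.edges, key=lambda e: (pg.edge_length(e), e))
    uf = _UnionFind(pg.coords)
    tree = set()
    for e in order:
        if uf.union(*e):
            tree.add(e)
    return tree


def fundamental_cycles(pg: PlanarGraph) -> list[list[int]]:
    """Cycle basis from a minimum spanning forest.

    For every non-tree edge {vi, vj} the (unique, hence shortest-weighted)
    tree path vi..vj closed by the edge gives one cycle, returned as a closed
    vertex walk.  Per component the count equals |E| - |V| + 1.
    """
    tree = minimum_spanning_forest(pg)
    tg = nx.Graph()
    tg.add_nodes_from(pg.coords)
    tg.add_edges_from(tree)
    cycles = []
    for e in sorted(pg.edges - tree):
        vi, vj = e
        path = nx.shortest_path(tg, vi, vj)
        cycles.append(path + [vi])
    return cycles


def enclosure_classes(
    marker_coords: dict[int, np.ndarray],
    cycles: list[list[int]],
    pg: PlanarGraph,
) -> list[dict]:
    """Group marker cells by the exact set of cycles containing them.

    Cells inside no cycle are dropped; the remaining classes are disjoint by
    construction.  Each class is ``{"members": frozenset, "cycles": frozenset}``.
    """
    containment: dict[int, frozenset] = {}
    polys = [np.asarray([pg.coords[v] for v in c]) for c in cycles]
    for mid, mc in marker_coords.items():
        inside = frozenset(
            k for k, poly in enumerate(polys) if winding_number(mc, poly) != 0
        )
        if inside:
            containment[mid] = inside
    groups: dict[frozenset, set[int]] = {}
    for mid, key in containment.items():
        groups.setdefault(key, set()).add(mid)
    return [
        {"members": frozenset(members), "cycles": key}
        for key, members in sorted(groups.items(), key=lambda kv: sorted(kv[1]))
    ]


def _min_turn_walk(
    pg: PlanarGraph,
    adjacency: dict[int, list[int]],
    v_star: int,
    theta_star: float,
    max_steps: int,
    mirror_start: bool = False,
) -> list[int] | None:
    """Trace the minimal-counterclockwise-turn closed walk from v_star.

    At each vertex the next neighbor is the one whose angle is the smallest
    angle strictly greater than the reference angle (the angle of the
    previous vertex as seen from the current one), wrapping to the smallest
    angle when none is greater.  This traces one face of the planar
    subdivision per starting edge; ``mirror_start`` picks the first edge by
    rotating clockwise instead of counterclockwise from theta_star, which
    starts the walk onto the face on the other side of the marker direction
    (needed when chords split the enclosing region into several faces).
    """

    def next_vertex(current: int, ref_angle: float) -> int | None:
        nbrs = adjacency[current]
        if not nbrs:
            return None
        angles = sorted(
            (angle(pg.coords[w], pg.coords[current]), w) for w in nbrs
        )
        for a, w in angles:
            if a > ref_angle:
                return w
        return angles[0][1]

    def prev_vertex(current: int, ref_angle: float) -> int | None:
        nbrs = adjacency[current]
        if not nbrs:
            return None
        angles = sorted(
            (angle(pg.coords[w], pg.coords[current]), w) for w in nbrs
        )
        for a, w in reversed(angles):
            if a < ref_angle:
                return w
        return angles[-1][1]

    walk = [v_star]
    v1 = (
        prev_vertex(v_star, theta_star)
        if mirror_start
        else next_vertex(v_star, theta_star)
    )
    if v1 is None:
        return None
    walk.append(v1)
    while walk[-1] != v_star:
        if len(walk) > max_steps:
            return None
        prev, cur = walk[-2], walk[-1]
        ref = angle(pg.coords[prev], pg.coords[cur])
        nxt = next_vertex(cur, ref)
        if nxt is None:
            return None
        walk.append(nxt)
    return walk


def minimal_enclosing_cycle(
    members: frozenset[int],
    marker_coords: dict[int, np.ndarray],
    pg: PlanarGraph,
    component_id: int = 0,
) -> GeometricCycle | None:
    """Minimal counterclockwise-turn cycle of structure cells around the
    marker set ``members``.

    Anchors are tried in order of marker-to-structure-vertex distance (ties
    by id pair).  A candidate walk is accepted only if every member has
    nonzero winding number; failing pairs are marked incompatible and the
    next closest pair is tried.  Returns None when all pairs are exhausted.
    """
    if not members:
        raise ValueError("empty enclosure class")
    adjacency: dict[int, list[int]] = {v: [] for v in pg.coords}
    for u, v in pg.edges:
        adjacency[u].append(v)
        adjacency[v].append(u)
    candidates = sorted(
        (
            float(np.linalg.norm(marker_coords[m] - pg.coords[v])),
            m,
            v,
        )
        for m in sorted(members)
        for v in pg.coords
    )
    max_steps = 2 * max(1, len(pg.edges))
    for _dist, m, v_star in candidates:
        theta_star = angle(marker_coords[m], pg.coords[v_star])
        # the paper-order start first; the mirror start (clockwise rotation
        # from the marker direction) before marking the pair incompatible
        for mirror in (False, True):
            walk = _min_turn_walk(
                pg, adjacency, v_star, theta_star, max_steps, mirror_start=mirror
            )
            if walk is None or len(walk) < 4:
                continue
            poly = np.asarray([pg.coords[v] for v in walk])
            if not all(
                winding_number(marker_coords[s], poly) != 0 for s in members
            ):
                continue
            prov = {v: pg.dummy_origin[v] for v in walk if v in pg.dummy_origin}
            support: set[int] = set()
            for a, b in zip(walk, walk[1:]):
                e = (min(a, b), max(a, b))
                support.update(pg.edge_source.get(e, e))
            support &= pg.real_ids
            return GeometricCycle(
                walk=walk,
                enclosed=frozenset(members),
                component_id=component_id,
                dummy_provenance=prov,
                support=frozenset(support),
            )
    return None


def find_geometric_cycles(
    structure_graph: CellTypeGraph,
    marker_ids: list[int],
    marker_coords: np.ndarray,
) -> tuple[list[GeometricCycle], list[dict], PlanarGraph]:
    """Full geometric pipeline for one islet and one direction.

    Returns the minimal enclosing cycle per enclosure class, the enclosure
    classes themselves, and the planarized structure graph.
    """
    pg = planarize(structure_graph)
    cycles = fundamental_cycles(pg)
    mcoords = {
        i: np.asarray(c, dtype=float) for i, c in zip(marker_ids, marker_coords)
    }
    classes = enclosure_classes(mcoords, cycles, pg)
    comp_of = {}
    for k, comp in enumerate(nx.connected_components(pg.to_networkx())):
        for v in comp:
            comp_of[v] = k
    out = []
    for cls in classes:
        anchor_cycle = min(cls["cycles"])
        comp_id = comp_of.get(cycles[anchor_cycle][0], 0)
        gc = minimal_enclosing_cycle(cls["members"], mcoords, pg, comp_id)
        if gc is not None:
            out.append(gc)
    return out, classes, pg
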