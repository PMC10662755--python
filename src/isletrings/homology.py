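"""Dimension-1 (and, in 3D, dimension-2) persistent homology with
representative boundaries.

Simplices are totally ordered by spatial scale (edge length; a triangle by
its largest-order boundary edge; a tetrahedron by its diameter, the longest
edge among its faces) and the boundary matrices are reduced over GF(2) by
the standard column algorithm.  A pivot (i, j) of the reduced triangle
matrix pairs a feature born at the scale of edge i with its death at the
scale of triangle j.  Biologically significant features are the ones that
never die because the fill simplices that would kill them contain marker
cells and are excluded from the filtration; their representatives are read
from the corresponding columns of the operation log V.

Columns are stored as Python integers used as GF(2) bit vectors; bit i of a
column is its row-i entry, so the pivot is simply ``bit_length() - 1``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

#: when True every reduction re-checks R = D.V, V unit upper-triangular and
#: pivot uniqueness (enabled for the whole test suite)
VALIDATE = False


class ReductionInvariantError(AssertionError):
    pass


class BoundaryConsistencyError(RuntimeError):
    """A qualifying V-column did not assemble into a closed cycle/surface."""


@dataclass
class Filtration:
    """Totally ordered simplices of one structure-cell class.

    ``edges[k]`` / ``triangles[k]`` / ``tetrahedra[k]`` hold vertex-id tuples
    in filtration order; the parallel ``*_scales`` arrays hold their spatial
    scales.
    """

    vertex_ids: list[int]
    coords: dict[int, np.ndarray]
    edges: list[tuple[int, int]]
    edge_scales: list[float]
    triangles: list[tuple[int, int, int]]
    triangle_scales: list[float]
    tetrahedra: list[tuple[int, int, int, int]] = field(default_factory=list)
    tetrahedron_scales: list[float] = field(default_factory=list)


@dataclass
class ReducedBoundaryMatrix:
    """Reduction R = D.V over GF(2) with the column-operation log V."""

    D: list[int]
    R: list[int]
    V: list[int]
    n_rows: int

    @property
    def pivots(self) -> list[tuple[int, int]]:
        return [
            (c.bit_length() - 1, j) for j, c in enumerate(self.R) if c
        ]

    @property
    def pivot_rows(self) -> set[int]:
        return {c.bit_length() - 1 for c in self.R if c}


@dataclass(frozen=True)
class PersistencePair:
    dimension: int
    birth: float
    death: float | None  # None: undying

    @property
    def persistence(self) -> float:
        if self.death is None:
            return math.inf
        return self.death - self.birth


@dataclass
class RepresentativeBoundary:
    """Edge set (2D) or triangle set (3D) of an undying feature."""

    simplices: frozenset[tuple]
    enclosed: frozenset[int]
    birth: float

    @property
    def edge_count(self) -> int:
        return len(self.simplices)


def check_reduction(red: ReducedBoundaryMatrix) -> None:
    """Assert R = D.V over GF(2), V unit upper-triangular, pivots unique."""
    n = len(red.D)
    for j in range(n):
        if not (red.V[j] >> j) & 1:
            raise ReductionInvariantError("V diagonal entry is zero")
        if red.V[j] >> (j + 1):
            raise ReductionInvariantError("V is not upper-triangular")
        acc = 0
        v = red.V[j]
        while v:
            i = v.bit_length() - 1
            acc ^= red.D[i]
            v ^= 1 << i
        if acc != red.R[j]:
            raise ReductionInvariantError("R != D.V over GF(2)")
    rows = [c.bit_length() - 1 for c in red.R if c]
    if len(rows) != len(set(rows)):
        raise ReductionInvariantError("duplicate pivot rows")


def reduce(columns: list[int], n_rows: int) -> ReducedBoundaryMatrix:
    """Standard column reduction over GF(2).

    Left to right, while a column shares its pivot (the maximum row index
    with a nonzero entry) with an earlier column, the earlier column is
    added into it; V logs every addition.
    """
    R = list(columns)
    V = [1 << j for j in range(len(columns))]
    owner: dict[int, int] = {}
    for j in range(len(R)):
        while R[j]:
            p = R[j].bit_length() - 1
            i = owner.get(p)
            if i is None:
                owner[p] = j
                break
            R[j] ^= R[i]
            V[j] ^= V[i]
    red = ReducedBoundaryMatrix(D=list(columns), R=R, V=V, n_rows=n_rows)
    if VALIDATE:
        check_reduction(red)
    return red


# ---------------------------------------------------------------------------
# containment predicates
# ---------------------------------------------------------------------------

def point_in_triangle(point, tri, tol: float = 1e-12) -> bool:
    """Horizontal-ray crossing parity; boundary points count as contained.

    Degenerate (zero-area) triangles contain nothing.
    """
    p = np.asarray(point, dtype=float)
    verts = [np.asarray(v, dtype=float) for v in tri]
    a, b, c = verts
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    scale = max(1.0, float(np.max(np.abs(np.vstack(verts)))))
    if area2 <= tol * scale * scale:
        return False
    from .geometric import _on_segment

    for u, v in ((a, b), (b, c), (c, a)):
        if _on_segment(p, u, v):
            return True
    crossings = 0
    for u, v in ((a, b), (b, c), (c, a)):
        if (u[1] > p[1]) != (v[1] > p[1]):
            x = u[0] + (p[1] - u[1]) * (v[0] - u[0]) / (v[1] - u[1])
            if x > p[0]:
                crossings += 1
    return crossings % 2 == 1


def point_in_tetrahedron(point, tet, tol: float = 1e-9) -> bool:
    """Barycentric containment; boundary (faces, edges, vertices) counts as
    contained; degenerate (coplanar) tetrahedra contain nothing."""
    p = np.asarray(point, dtype=float)
    v = [np.asarray(x, dtype=float) for x in tet]
    T = np.column_stack([v[0] - v[3], v[1] - v[3], v[2] - v[3]])
    det = np.linalg.det(T)
    scale = max(1.0, float(np.max(np.abs(T)))) ** 3
    if abs(det) <= tol * scale:
        return False
    lam = np.linalg.solve(T, p - v[3])
    lam = np.append(lam, 1.0 - lam.sum())
    return bool(np.all(lam >= -tol) and np.all(lam <= 1 + tol))


def point_in_triangle_3d(point, tri, tol: float = 1e-9) -> bool:
    """Exact 3D triangle containment: the point lies in the triangle's plane
    and inside (or on) the triangle.  For generic point clouds this is a
    measure-zero event; it matters for exactly symmetric configurations
    where a fill triangle passes through a marker cell."""
    p = np.asarray(point, dtype=float)
    a, b, c = (np.asarray(v, dtype=float) for v in tri)
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn <= tol:
        return False
    if abs(float((p - a) @ n)) / nn > tol * max(1.0, float(np.abs([a, b, c]).max())):
        return False
    # inside test via barycentric coordinates in the plane
    m = np.column_stack([b - a, c - a])
    sol, *_ = np.linalg.lstsq(m, p - a, rcond=None)
    s, t = float(sol[0]), float(sol[1])
    return s >= -tol and t >= -tol and s + t <= 1 + tol


# ---------------------------------------------------------------------------
# filtration construction
# ---------------------------------------------------------------------------

def _order_edges(
    coords: dict[int, np.ndarray], pairs: list[tuple[int, int]]
) -> tuple[list[tuple[int, int]], list[float]]:
    keyed = sorted(
        (float(np.linalg.norm(coords[a] - coords[b])), a, b)
        for a, b in (tuple(sorted(p)) for p in pairs)
    )
    return [(a, b) for _, a, b in keyed], [l for l, _, _ in keyed]


def build_filtration_2d(
    structure_ids: list[int],
    coords: dict[int, np.ndarray],
    marker_coords: np.ndarray | None = None,
    edges: set[tuple[int, int]] | None = None,
    exclude_marked: bool = False,
    edge_order: list[tuple[int, int]] | None = None,
) -> Filtration:
    """2D filtration: edges by length, triangles by their largest-order edge.

    ``edges=None`` takes every pairwise edge (full clique, used for plain
    max-persistence); otherwise only the supplied graph edges enter, which is
    the significant-cycle mode.  ``exclude_marked`` drops triangles that
    contain a marker cell (horizontal-ray test, boundary inclusive), the
    forbidden fill simplices.  ``edge_order`` overrides the length sort (for
    stochastic tie-order resampling); it must list the same edge set.
    """
    ids = sorted(structure_ids)
    if edges is None:
        pairs = [tuple(sorted(p)) for p in itertools.combinations(ids, 2)]
    else:
        pairs = [tuple(sorted(e)) for e in edges]
    if edge_order is not None:
        if {tuple(sorted(e)) for e in edge_order} != set(pairs):
            raise ValueError("edge_order must be a permutation of the edge set")
        e_list = [tuple(sorted(e)) for e in edge_order]
        e_scales = [float(np.linalg.norm(coords[a] - coords[b])) for a, b in e_list]
    else:
        e_list, e_scales = _order_edges(coords, pairs)
    pos = {e: k for k, e in enumerate(e_list)}
    tris = []
    for a, b, c in itertools.combinations(ids, 3):
        e1, e2, e3 = (a, b), (a, c), (b, c)
        if e1 in pos and e2 in pos and e3 in pos:
            if exclude_marked and marker_coords is not None and any(
                point_in_triangle(m, (coords[a], coords[b], coords[c]))
                for m in marker_coords
            ):
                continue
            key = tuple(sorted((pos[e1], pos[e2], pos[e3]), reverse=True))
            tris.append((key, (a, b, c)))
    tris.sort()
    t_list = [t for _, t in tris]
    t_scales = [e_scales[key[0]] for key, _ in tris]
    return Filtration(
        vertex_ids=ids,
        coords=coords,
        edges=e_list,
        edge_scales=e_scales,
        triangles=t_list,
        triangle_scales=t_scales,
    )


def build_filtration_3d(
    structure_ids: list[int],
    coords: dict[int, np.ndarray],
    marker_coords: np.ndarray | None = None,
    edge_threshold: float = 25.0,
    exclude_marked_triangles: bool = True,
) -> Filtration:
    """3D filtration under a fixed edge-length threshold (default 25, in the
    units of the source volumes).

    Triangles need all three edges present; tetrahedra need all four faces
    valid and must not contain a marker cell (barycentric test).  Triangles
    that contain a marker exactly (in-plane) are likewise excluded by
    default; for generic data this is vacuous but it keeps exactly
    symmetric shells (markers in a fill triangle's plane) behaving like the
    2D rule.
    """
    ids = sorted(structure_ids)
    pairs = [
        (a, b)
        for a, b in itertools.combinations(ids, 2)
        if np.linalg.norm(coords[a] - coords[b]) <= edge_threshold
    ]
    e_list, e_scales = _order_edges(coords, pairs)
    pos = {e: k for k, e in enumerate(e_list)}
    tris = []
    for a, b, c in itertools.combinations(ids, 3):
        es = ((a, b), (a, c), (b, c))
        if all(e in pos for e in es):
            if exclude_marked_triangles and marker_coords is not None and any(
                point_in_triangle_3d(m, (coords[a], coords[b], coords[c]))
                for m in marker_coords
            ):
                continue
            key = tuple(sorted((pos[e] for e in es), reverse=True))
            tris.append((key, (a, b, c)))
    tris.sort()
    t_list = [t for _, t in tris]
    t_scales = [e_scales[key[0]] for key, _ in tris]
    t_pos = {t: k for k, t in enumerate(t_list)}
    tets = []
    for quad in itertools.combinations(ids, 4):
        faces = list(itertools.combinations(quad, 3))
        if not all(f in t_pos for f in faces):
            continue
        if marker_coords is not None and any(
            point_in_tetrahedron(m, tuple(coords[v] for v in quad))
            for m in marker_coords
        ):
            continue
        edge_positions = sorted(
            (pos[e] for e in itertools.combinations(quad, 2)), reverse=True
        )
        tets.append((tuple(edge_positions), quad))
    tets.sort()
    h_list = [q for _, q in tets]
    h_scales = [e_scales[key[0]] for key, _ in tets]
    return Filtration(
        vertex_ids=ids,
        coords=coords,
        edges=e_list,
        edge_scales=e_scales,
        triangles=t_list,
        triangle_scales=t_scales,
        tetrahedra=h_list,
        tetrahedron_scales=h_scales,
    )


# ---------------------------------------------------------------------------
# boundary matrices and persistence
# ---------------------------------------------------------------------------

def _edge_boundary_columns(filt: Filtration) -> tuple[list[int], int]:
    vpos = {v: k for k, v in enumerate(filt.vertex_ids)}
    cols = [(1 << vpos[a]) | (1 << vpos[b]) for a, b in filt.edges]
    return cols, len(filt.vertex_ids)


def _triangle_boundary_columns(filt: Filtration) -> tuple[list[int], int]:
    epos = {e: k for k, e in enumerate(filt.edges)}
    cols = []
    for a, b, c in filt.triangles:
        col = 0
        for e in ((a, b), (a, c), (b, c)):
            col |= 1 << epos[e]
        cols.append(col)
    return cols, len(filt.edges)


def _tetra_boundary_columns(filt: Filtration) -> tuple[list[int], int]:
    tpos = {t: k for k, t in enumerate(filt.triangles)}
    cols = []
    for quad in filt.tetrahedra:
        col = 0
        for f in itertools.combinations(quad, 3):
            col |= 1 << tpos[f]
        cols.append(col)
    return cols, len(filt.triangles)


def persistence_pairs_dim1(filt: Filtration) -> list[PersistencePair]:
    """Dimension-1 pairs: pivot (i, j) of the reduced triangle matrix pairs a
    feature born at edge i's length with death at triangle j's scale; creator
    edges never killed are undying pairs (death None)."""
    De, n_v = _edge_boundary_columns(filt)
    Dt, n_e = _triangle_boundary_columns(filt)
    Re = reduce(De, n_v)
    Rt = reduce(Dt, n_e)
    pairs = [
        PersistencePair(1, filt.edge_scales[i], filt.triangle_scales[j])
        for i, j in Rt.pivots
    ]
    killed = Rt.pivot_rows
    for i, col in enumerate(Re.R):
        if col == 0 and i not in killed:
            pairs.append(PersistencePair(1, filt.edge_scales[i], None))
    return pairs


def max_h1_persistence(coords: np.ndarray) -> float:
    """Maximum finite dimension-1 persistence of the full clique filtration
    on one class's cells; 0 with fewer than three cells or no cycles."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if n < 3:
        return 0.0
    cdict = {k: coords[k] for k in range(n)}
    filt = build_filtration_2d(list(range(n)), cdict)
    finite = [p.persistence for p in persistence_pairs_dim1(filt) if p.death is not None]
    return max(finite, default=0.0)


def _edge_set_closed(edge_set) -> bool:
    deg: dict[int, int] = {}
    for a, b in edge_set:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    return all(d % 2 == 0 for d in deg.values())


def enclosed_markers_2d(
    edge_set,
    coords: dict[int, np.ndarray],
    marker_ids: list[int],
    marker_coords: np.ndarray,
) -> frozenset[int]:
    """Markers enclosed by a GF(2) 1-cycle, by even-odd ray-crossing parity
    against the whole edge set (well defined for any union of loops; equals
    the winding parity over the cycle's simple-loop decomposition).  Markers
    exactly on an edge count as not enclosed."""
    from .geometric import _on_segment

    segs = [(coords[a], coords[b]) for a, b in edge_set]
    inside = set()
    for mid, m in zip(marker_ids, marker_coords):
        m = np.asarray(m, dtype=float)
        if any(_on_segment(m, u, v) for u, v in segs):
            continue
        crossings = 0
        for u, v in segs:
            if (u[1] > m[1]) != (v[1] > m[1]):
                x = u[0] + (m[1] - u[1]) * (v[0] - u[0]) / (v[1] - u[1])
                if x > m[0]:
                    crossings += 1
        if crossings % 2 == 1:
            inside.add(mid)
    return frozenset(inside)


def _undying_columns(Re: ReducedBoundaryMatrix, Rt: ReducedBoundaryMatrix):
    killed = Rt.pivot_rows
    return [i for i, col in enumerate(Re.R) if col == 0 and i not in killed]


def significant_cycles_2d(
    structure_ids: list[int],
    coords: dict[int, np.ndarray],
    edges: set[tuple[int, int]],
    marker_ids: list[int],
    marker_coords: np.ndarray,
    edge_order: list[tuple[int, int]] | None = None,
) -> list[RepresentativeBoundary]:
    """Representative boundaries of undying features of the class graph.

    Edges are the tau-and-shadow graph edges; triangles are restricted to
    those edges and to triangles free of marker cells.  A column i of the
    reduced edge matrix that is empty and is not a pivot row of the reduced
    triangle matrix marks an undying feature; column i of V_e is its
    representative edge set.  Boundaries that enclose no marker are
    discarded.
    """
    filt = build_filtration_2d(
        structure_ids,
        coords,
        marker_coords=np.atleast_2d(np.asarray(marker_coords, dtype=float))
        if len(marker_ids)
        else None,
        edges=edges,
        exclude_marked=True,
        edge_order=edge_order,
    )
    De, n_v = _edge_boundary_columns(filt)
    Dt, n_e = _triangle_boundary_columns(filt)
    Re = reduce(De, n_v)
    Rt = reduce(Dt, n_e)
    out = []
    for i in _undying_columns(Re, Rt):
        v = Re.V[i]
        edge_idx = []
        while v:
            k = v.bit_length() - 1
            edge_idx.append(k)
            v ^= 1 << k
        simplices = frozenset(filt.edges[k] for k in edge_idx)
        if not _edge_set_closed(simplices):
            raise BoundaryConsistencyError(
                "representative edge set is not a GF(2) cycle"
            )
        enclosed = enclosed_markers_2d(simplices, coords, marker_ids, marker_coords)
        if enclosed:
            out.append(
                RepresentativeBoundary(
                    simplices=simplices,
                    enclosed=enclosed,
                    birth=filt.edge_scales[i],
                )
            )
    return out


# ---------------------------------------------------------------------------
# 3D voids
# ---------------------------------------------------------------------------

_RAY_DIRECTIONS = [
    np.array([0.5773502691896258, 0.5773502691896258, 0.5773502691896258]),
    np.array([0.8017837257372732, 0.5345224838248488, 0.2672612419124244]),
    np.array([0.1690308509457033, 0.50709255283711, 0.8451542547285166]),
    np.array([0.9116846116771036, 0.3010430687577853, 0.2795399923893792]),
]


def _ray_hits_triangle(origin, direction, tri, eps=1e-10):
    """Moller-Trumbore; returns (hit, robust).  robust=False flags grazing
    intersections near the triangle border so callers can switch rays."""
    v0, v1, v2 = (np.asarray(v, dtype=float) for v in tri)
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = float(e1 @ h)
    if abs(a) < eps:
        return False, True
    f = 1.0 / a
    s = origin - v0
    u = f * float(s @ h)
    q = np.cross(s, e1)
    v = f * float(direction @ q)
    t = f * float(e2 @ q)
    hit = (0.0 <= u <= 1.0) and (0.0 <= v <= 1.0) and (u + v <= 1.0) and t > eps
    near_border = (
        min(abs(u), abs(v), abs(1 - u - v), abs(t)) < 1e-7
        and (-1e-7 <= u <= 1 + 1e-7)
        and (-1e-7 <= v <= 1 + 1e-7)
        and (u + v <= 1 + 1e-7)
    )
    return hit, not near_border


def _point_inside_surface(point, triangles, coords) -> bool:
    """Even-odd parity of ray-triangle crossings; retries with alternate ray
    directions when a crossing grazes a triangle border."""
    origin = np.asarray(point, dtype=float)
    for direction in _RAY_DIRECTIONS:
        crossings = 0
        ok = True
        for tri in triangles:
            hit, robust = _ray_hits_triangle(
                origin, direction, tuple(coords[v] for v in tri)
            )
            if not robust:
                ok = False
                break
            if hit:
                crossings += 1
        if ok:
            return crossings % 2 == 1
    # all rays grazed: fall back to the last parity computed
    return crossings % 2 == 1


def _triangle_set_closed(triangles) -> bool:
    deg: dict[tuple, int] = {}
    for t in triangles:
        for e in itertools.combinations(sorted(t), 2):
            deg[e] = deg.get(e, 0) + 1
    return all(d % 2 == 0 for d in deg.values())


def significant_voids_3d(
    structure_ids: list[int],
    coords: dict[int, np.ndarray],
    marker_ids: list[int],
    marker_coords: np.ndarray,
    edge_threshold: float = 25.0,
) -> list[RepresentativeBoundary]:
    """Closed triangulated surfaces of undying dimension-2 features in 3D.

    Tetrahedra containing marker cells are forbidden fills, so voids that
    hold markers never die; a column i of the reduced triangle matrix that is
    empty and not a pivot row of the reduced tetrahedron matrix yields
    column i of V_t as a representative surface.  Surfaces enclosing no
    marker (3D ray-casting parity) are discarded.
    """
    mc = np.atleast_2d(np.asarray(marker_coords, dtype=float)) if len(marker_ids) else None
    filt = build_filtration_3d(
        structure_ids, coords, marker_coords=mc, edge_threshold=edge_threshold
    )
    Dt, n_e = _triangle_boundary_columns(filt)
    Dh, n_t = _tetra_boundary_columns(filt)
    Rt = reduce(Dt, n_e)
    Rh = reduce(Dh, n_t)
    killed = Rh.pivot_rows
    out = []
    for i, col in enumerate(Rt.R):
        if col != 0 or i in killed:
            continue
        v = Rt.V[i]
        tri_idx = []
        while v:
            k = v.bit_length() - 1
            tri_idx.append(k)
            v ^= 1 << k
        triangles = frozenset(filt.triangles[k] for k in tri_idx)
        if not _triangle_set_closed(triangles):
            raise BoundaryConsistencyError(
                "representative triangle set is not a closed surface"
            )
        enclosed = frozenset(
            mid
            for mid, m in zip(marker_ids, marker_coords)
            if _point_inside_surface(m, triangles, coords)
        )
        if enclosed:
            out.append(
                RepresentativeBoundary(
                    simplices=triangles,
                    enclosed=enclosed,
                    birth=filt.triangle_scales[i],
                )
            )
    return out
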