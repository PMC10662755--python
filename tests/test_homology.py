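"""Filtrations, GF(2) reduction, persistence pairs and significant cycles."""

import itertools
import math

import numpy as np
import pytest

from conftest import gf2_rank, oracle_pairs_dim1
from isletrings import homology as H
from isletrings import gen_shell3d
from isletrings.homology import (
    build_filtration_2d,
    build_filtration_3d,
    check_reduction,
    max_h1_persistence,
    persistence_pairs_dim1,
    point_in_tetrahedron,
    point_in_triangle,
    reduce,
    significant_cycles_2d,
    significant_voids_3d,
)


def _cdict(pts):
    return {k: np.asarray(p, dtype=float) for k, p in enumerate(pts)}


class TestFiltration2D:
    def test_three_points(self):
        coords = _cdict([(0, 0), (3, 0), (0, 4)])
        filt = build_filtration_2d([0, 1, 2], coords)
        assert filt.edge_scales == sorted(filt.edge_scales) == [3.0, 4.0, 5.0]
        assert len(filt.triangles) == 1
        assert filt.triangle_scales == [5.0]  # follows its longest edge

    def test_marker_excludes_triangle(self):
        coords = _cdict([(0, 0), (3, 0), (0, 4)])
        filt = build_filtration_2d(
            [0, 1, 2],
            coords,
            marker_coords=np.array([[0.8, 0.8]]),
            exclude_marked=True,
        )
        assert filt.triangles == []

    def test_orders_match_resort_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 20, size=(10, 2))
        coords = _cdict(pts)
        filt = build_filtration_2d(list(range(10)), coords)
        # oracle: sort edges by (length, ids) independently
        want = sorted(
            (float(np.linalg.norm(pts[i] - pts[j])), i, j)
            for i, j in itertools.combinations(range(10), 2)
        )
        assert [(a, b) for _, a, b in want] == filt.edges
        # triangles sorted by position of their largest-order edge
        pos = {e: k for k, e in enumerate(filt.edges)}
        keys = [
            max(pos[(a, b)], pos[(a, c)], pos[(b, c)])
            for a, b, c in filt.triangles
        ]
        assert keys == sorted(keys)
        # every triangle's edges precede it in scale
        for (a, b, c), s in zip(filt.triangles, filt.triangle_scales):
            assert s == max(
                filt.edge_scales[pos[(a, b)]],
                filt.edge_scales[pos[(a, c)]],
                filt.edge_scales[pos[(b, c)]],
            )


class TestPointInTriangle:
    def test_centroid_inside(self):
        tri = (np.array([0.0, 0]), np.array([4.0, 0]), np.array([0.0, 3]))
        assert point_in_triangle(np.array([4 / 3, 1.0]), tri)

    def test_outside_bbox(self):
        tri = (np.array([0.0, 0]), np.array([4.0, 0]), np.array([0.0, 3]))
        assert not point_in_triangle(np.array([10.0, 10.0]), tri)

    def test_boundary_counts_contained(self):
        tri = (np.array([0.0, 0]), np.array([4.0, 0]), np.array([0.0, 3]))
        assert point_in_triangle(np.array([2.0, 0.0]), tri)
        assert point_in_triangle(np.array([0.0, 0.0]), tri)

    def test_degenerate_contains_nothing(self):
        tri = (np.array([0.0, 0]), np.array([1.0, 1]), np.array([2.0, 2]))
        assert not point_in_triangle(np.array([1.0, 1.0]), tri)

    def test_matches_barycentric_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            tri = rng.uniform(0, 10, size=(3, 2))
            p = rng.uniform(0, 10, size=2)
            T = np.column_stack([tri[0] - tri[2], tri[1] - tri[2]])
            det = np.linalg.det(T)
            if abs(det) < 1e-6:
                continue
            lam = np.linalg.solve(T, p - tri[2])
            lam = np.append(lam, 1 - lam.sum())
            if np.min(np.abs(lam)) < 1e-9 or np.min(np.abs(1 - lam)) < 1e-9:
                continue  # skip boundary-grazing cases
            want = bool(np.all(lam > 0))
            assert point_in_triangle(p, tuple(tri)) == want


class TestReduce:
    def test_distinct_pivots_identity(self):
        cols = [0b001, 0b010, 0b100]
        red = reduce(cols, 3)
        assert red.R == cols
        assert red.V == [1, 2, 4]

    def test_duplicate_column_zeroed(self):
        cols = [0b011, 0b011]
        red = reduce(cols, 2)
        assert red.R[1] == 0
        assert red.V[1] == 0b11

    def test_random_matrices_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_rows = int(rng.integers(3, 12))
            n_cols = int(rng.integers(1, 20))
            cols = [
                int.from_bytes(rng.bytes(4), "little") & ((1 << n_rows) - 1)
                for _ in range(n_cols)
            ]
            red = reduce(cols, n_rows)
            check_reduction(red)  # R = D.V, V unit upper-triangular, pivots unique
            # rank preserved
            assert gf2_rank(red.R) == gf2_rank(cols)


class TestPersistencePairs:
    def test_unit_square_closed_form(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        filt = build_filtration_2d([0, 1, 2, 3], _cdict(pts))
        pairs = [p for p in persistence_pairs_dim1(filt) if p.death is not None]
        pos = [p for p in pairs if p.persistence > 1e-12]
        assert len(pos) == 1
        assert pos[0].birth == pytest.approx(1.0)
        assert pos[0].death == pytest.approx(math.sqrt(2))
        assert abs(pos[0].persistence - (math.sqrt(2) - 1)) < 1e-9

    def test_345_triangle_zero_persistence(self):
        filt = build_filtration_2d([0, 1, 2], _cdict([(0, 0), (3, 0), (0, 4)]))
        (pair,) = persistence_pairs_dim1(filt)
        assert pair.birth == pair.death == 5.0
        assert pair.persistence == 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_random_clouds_match_rank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        pts = rng.uniform(0, 10, size=(n, 2))
        filt = build_filtration_2d(list(range(n)), _cdict(pts))
        got = sorted(
            (round(p.birth, 9), round(p.death, 9))
            for p in persistence_pairs_dim1(filt)
            if p.death is not None
        )
        finite, undying = oracle_pairs_dim1(filt)
        assert got == sorted((round(b, 9), round(d, 9)) for b, d in finite)
        assert undying == []  # clique filtrations kill every 1-cycle


class TestMaxPersistence:
    def test_collinear_zero(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float)
        assert max_h1_persistence(pts) == 0.0

    def test_too_few_points(self):
        assert max_h1_persistence(np.array([[0.0, 0], [1, 1]])) == 0.0

    def test_ring_matches_oracle(self):
        th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th)])
        filt = build_filtration_2d(list(range(12)), _cdict(pts))
        finite, _ = oracle_pairs_dim1(filt)
        want = max(d - b for b, d in finite)
        assert max_h1_persistence(pts) == pytest.approx(want)
        # the dominant feature is born at the ring chord length
        assert max_h1_persistence(pts) > 5.0


def _square_ring(side=10.0):
    pts = [(0, 0), (side, 0), (side, side), (0, side)]
    coords = _cdict(pts)
    edges = {(0, 1), (1, 2), (2, 3), (0, 3)}
    return coords, edges


class TestSignificantCycles2D:
    def test_square_ring_with_marker(self):
        coords, edges = _square_ring()
        out = significant_cycles_2d(
            [0, 1, 2, 3], coords, edges, [9], np.array([[5.0, 5.0]])
        )
        assert len(out) == 1
        assert out[0].enclosed == frozenset({9})
        assert out[0].edge_count == 4

    def test_square_ring_without_marker_discarded(self):
        coords, edges = _square_ring()
        out = significant_cycles_2d([0, 1, 2, 3], coords, edges, [], np.empty((0, 2)))
        assert out == []

    def test_two_disjoint_rings(self):
        coords, edges = _square_ring()
        far = {k + 4: np.asarray(p, float) + 100.0 for k, p in enumerate(
            [(0, 0), (10, 0), (10, 10), (0, 10)]
        )}
        coords.update(far)
        edges = edges | {(4, 5), (5, 6), (6, 7), (4, 7)}
        markers = np.array([[5.0, 5.0], [105.0, 105.0]])
        out = significant_cycles_2d(
            list(range(8)), coords, edges, [50, 51], markers
        )
        assert len(out) == 2
        assert {b.enclosed for b in out} == {frozenset({50}), frozenset({51})}

    def test_representative_is_gf2_cycle(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 30, size=(12, 2))
        coords = _cdict(pts)
        edges = {
            (i, j)
            for i, j in itertools.combinations(range(12), 2)
            if np.linalg.norm(pts[i] - pts[j]) < 14
        }
        markers = rng.uniform(5, 25, size=(3, 2))
        out = significant_cycles_2d(list(range(12)), coords, edges, [90, 91, 92], markers)
        for b in out:
            deg = {}
            for u, v in b.simplices:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            assert all(d % 2 == 0 for d in deg.values())
            assert b.enclosed  # empty ones are discarded

    def test_monotone_in_marker_set(self):
        # adding markers can only forbid more fills: undying features grow
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 30, size=(14, 2))
        coords = _cdict(pts)
        edges = {
            (i, j)
            for i, j in itertools.combinations(range(14), 2)
            if np.linalg.norm(pts[i] - pts[j]) < 13
        }
        markers = rng.uniform(3, 27, size=(4, 2))

        def undying_count(mk):
            filt = build_filtration_2d(
                list(range(14)), coords,
                marker_coords=mk if len(mk) else None,
                edges=edges, exclude_marked=True,
            )
            De, nv = H._edge_boundary_columns(filt)
            Dt, ne = H._triangle_boundary_columns(filt)
            Re, Rt = reduce(De, nv), reduce(Dt, ne)
            return len(H._undying_columns(Re, Rt))

        counts = [undying_count(markers[:k]) for k in range(5)]
        assert counts == sorted(counts)


class TestPointInTetrahedron:
    TET = tuple(np.array(v, float) for v in [(0, 0, 0), (4, 0, 0), (0, 4, 0), (0, 0, 4)])

    def test_centroid(self):
        assert point_in_tetrahedron(np.array([1.0, 1, 1]), self.TET)

    def test_vertex_boundary_contained(self):
        assert point_in_tetrahedron(np.array([0.0, 0, 0]), self.TET)

    def test_outside(self):
        assert not point_in_tetrahedron(np.array([4.0, 4, 4]), self.TET)

    def test_degenerate_false(self):
        flat = tuple(np.array(v, float) for v in [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)])
        assert not point_in_tetrahedron(np.array([0.3, 0.3, 0.0]), flat)

    def test_matches_halfspace_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            tet = rng.uniform(0, 10, size=(4, 3))
            vol6 = np.linalg.det(np.column_stack([tet[0] - tet[3], tet[1] - tet[3], tet[2] - tet[3]]))
            if abs(vol6) < 1e-3:
                continue
            p = rng.uniform(0, 10, size=3)
            inside = True
            grazing = False
            for face in itertools.combinations(range(4), 3):
                (opp,) = set(range(4)) - set(face)
                a, b, c = tet[list(face)]
                n = np.cross(b - a, c - a)
                s_p = float(n @ (p - a))
                s_o = float(n @ (tet[opp] - a))
                if abs(s_p) < 1e-6:
                    grazing = True
                    break
                if s_p * s_o < 0:
                    inside = False
            if grazing:
                continue
            assert point_in_tetrahedron(p, tuple(tet)) == inside


class TestVoids3D:
    def test_filtration_tetra_inclusion(self):
        pts = [(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)]
        coords = _cdict(pts)
        filt = build_filtration_3d([0, 1, 2, 3], coords, edge_threshold=25.0)
        assert len(filt.tetrahedra) == 1
        # tetra ordered by its diameter (longest face edge)
        assert filt.tetrahedron_scales == [pytest.approx(10 * math.sqrt(2))]

    def test_filtration_marker_excludes_tetra(self):
        pts = [(0, 0, 0), (10, 0, 0), (0, 10, 0), (0, 0, 10)]
        coords = _cdict(pts)
        m = np.array([[2.5, 2.5, 2.5]])
        filt = build_filtration_3d([0, 1, 2, 3], coords, marker_coords=m, edge_threshold=25.0)
        assert filt.tetrahedra == []

    def test_octahedron_void(self):
        islet = gen_shell3d(1, "octahedron", 10.0, seed=0)
        s_ids, s_coords = islet.class_arrays("alphadelta")
        m_ids, m_coords = islet.class_arrays("beta")
        coords = {i: c for i, c in zip(s_ids, s_coords)}
        out = significant_voids_3d(s_ids, coords, m_ids, m_coords, 25.0)
        assert len(out) == 1
        assert len(out[0].simplices) == 8
        assert out[0].enclosed == frozenset(m_ids)

    def test_octahedron_no_marker_no_void(self):
        islet = gen_shell3d(0, "octahedron", 10.0, seed=0)
        s_ids, s_coords = islet.class_arrays("alphadelta")
        coords = {i: c for i, c in zip(s_ids, s_coords)}
        assert significant_voids_3d(s_ids, coords, [], np.empty((0, 3)), 25.0) == []

    def test_two_disjoint_shells(self):
        a = gen_shell3d(1, "octahedron", 10.0, seed=1)
        ids_a, c_a = a.class_arrays("alphadelta")
        m_a, mc_a = a.class_arrays("beta")
        coords = {i: c for i, c in zip(ids_a, c_a)}
        offset = np.array([100.0, 0.0, 0.0])
        b = gen_shell3d(1, "octahedron", 10.0, seed=2)
        ids_b, c_b = b.class_arrays("alphadelta")
        m_b, mc_b = b.class_arrays("beta")
        base = max(ids_a) + max(m_a) + 2
        coords.update({i + base: c + offset for i, c in zip(ids_b, c_b)})
        s_ids = ids_a + [i + base for i in ids_b]
        m_ids = m_a + [i + base for i in m_b]
        m_coords = np.vstack([mc_a, mc_b + offset])
        out = significant_voids_3d(s_ids, coords, m_ids, m_coords, 25.0)
        assert len(out) == 2
        assert {b.enclosed for b in out} == {
            frozenset({m_ids[0]}),
            frozenset({m_ids[1]}),
        }

    def test_surfaces_are_closed(self):
        islet = gen_shell3d(2, "icosahedron", 10.0, seed=4)
        s_ids, s_coords = islet.class_arrays("alphadelta")
        m_ids, m_coords = islet.class_arrays("beta")
        coords = {i: c for i, c in zip(s_ids, s_coords)}
        out = significant_voids_3d(s_ids, coords, m_ids, m_coords, 25.0)
        for surf in out:
            edge_deg = {}
            for t in surf.simplices:
                for e in itertools.combinations(sorted(t), 2):
                    edge_deg[e] = edge_deg.get(e, 0) + 1
            assert all(d % 2 == 0 for d in edge_deg.values())
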