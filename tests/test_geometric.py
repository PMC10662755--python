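"""Planarization, winding numbers and the minimal-turn enclosing walk."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_simple_polygon, ray_casting_inside, segments_properly_cross
from isletrings import (
    CellTypeGraph,
    DegenerateInputError,
    angle,
    build_class_graph,
    enclosure_classes,
    find_geometric_cycles,
    fundamental_cycles,
    gen_ring_islet,
    minimal_enclosing_cycle,
    planarize,
    winding_number,
)


def _graph(pts, edges):
    ids = list(range(len(pts)))
    return CellTypeGraph(
        cell_class="alphadelta",
        ids=ids,
        coords={i: np.asarray(p, float) for i, p in enumerate(pts)},
        edges={tuple(sorted(e)) for e in edges},
        tau=1e9,
    )


class TestAngle:
    @pytest.mark.parametrize(
        "v,u,expected",
        [
            ((1, 1), (0, 0), math.pi / 4),
            ((-1, 0), (0, 0), math.pi),
            ((0, -1), (0, 0), 3 * math.pi / 2),
            ((5, 0), (2, 0), 0.0),
        ],
    )
    def test_quadrants(self, v, u, expected):
        assert angle(np.array(v, float), np.array(u, float)) == pytest.approx(expected)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateInputError):
            angle(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    def test_range(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            v, u = rng.normal(size=2), rng.normal(size=2)
            if np.allclose(v, u):
                continue
            a = angle(v, u)
            assert 0 <= a < 2 * math.pi


class TestWinding:
    def test_ccw_square_centroid(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert winding_number(np.array([0.5, 0.5]), square) == 1

    def test_far_point(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert winding_number(np.array([10.0, 10.0]), square) == 0

    def test_boundary_point_not_enclosed(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert winding_number(np.array([0.5, 0.0]), square) == 0

    def test_cw_orientation_negative(self):
        square = np.array([[0, 0], [0, 1], [1, 1], [1, 0], [0, 0]], float)
        assert winding_number(np.array([0.5, 0.5]), square) == -1

    def test_matches_ray_casting(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            poly = random_simple_polygon(rng)
            p = rng.uniform(-12, 12, size=2)
            if any(
                abs((b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0]))
                < 1e-6
                for a, b in zip(poly[:-1], poly[1:])
            ):
                continue  # skip near-boundary cases
            assert (winding_number(p, poly) != 0) == ray_casting_inside(p, poly)


class TestPlanarize:
    def test_single_crossing(self):
        g = _graph(
            [(0, 0), (2, 2), (0, 2), (2, 0)], [(0, 1), (2, 3)]
        )
        pg = planarize(g)
        assert len(pg.dummy_origin) == 1
        (dummy,) = pg.dummy_origin
        np.testing.assert_allclose(pg.coords[dummy], [1, 1])
        assert len(pg.edges) == 4
        degree = sum(dummy in e for e in pg.edges)
        assert degree == 4

    def test_triangle_unchanged(self):
        g = _graph([(0, 0), (4, 0), (2, 3)], [(0, 1), (1, 2), (0, 2)])
        pg = planarize(g)
        assert pg.dummy_origin == {}
        assert pg.edges == g.edges

    def test_random_output_crossing_free(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 20, size=(10, 2))
        edges = set()
        while len(edges) < 15:
            i, j = sorted(rng.choice(10, size=2, replace=False))
            edges.add((int(i), int(j)))
        pg = planarize(_graph(pts, edges))
        for e1, e2 in itertools.combinations(sorted(pg.edges), 2):
            if set(e1) & set(e2):
                continue
            assert not segments_properly_cross(
                pg.coords[e1[0]], pg.coords[e1[1]], pg.coords[e2[0]], pg.coords[e2[1]]
            )

    def test_support_preserved(self):
        # sampled points of the original drawing lie on the new drawing
        g = _graph([(0, 0), (10, 10), (0, 10), (10, 0)], [(0, 1), (2, 3)])
        pg = planarize(g)
        for u, v in g.edges:
            for t in np.linspace(0, 1, 7):
                p = (1 - t) * g.coords[u] + t * g.coords[v]
                on_any = any(
                    abs(
                        (pg.coords[b][0] - pg.coords[a][0])
                        * (p[1] - pg.coords[a][1])
                        - (pg.coords[b][1] - pg.coords[a][1])
                        * (p[0] - pg.coords[a][0])
                    )
                    < 1e-9
                    and -1e-9
                    <= float((p - pg.coords[a]) @ (pg.coords[b] - pg.coords[a]))
                    <= float(
                        (pg.coords[b] - pg.coords[a]) @ (pg.coords[b] - pg.coords[a])
                    )
                    + 1e-9
                    for a, b in pg.edges
                )
                assert on_any


class TestFundamentalCycles:
    def test_tree_has_none(self):
        g = _graph([(0, 0), (1, 0), (2, 0), (1, 1)], [(0, 1), (1, 2), (1, 3)])
        assert fundamental_cycles(planarize(g)) == []

    def test_triangle_single_cycle(self):
        g = _graph([(0, 0), (4, 0), (2, 3)], [(0, 1), (1, 2), (0, 2)])
        (cycle,) = fundamental_cycles(planarize(g))
        assert cycle[0] == cycle[-1]
        assert len(set(cycle)) == 3

    def test_cyclomatic_count(self):
        # planar component with |E|=7, |V|=5 -> 3 independent cycles
        pts = [(0, 0), (4, 0), (4, 4), (0, 4), (2, 6)]
        edges = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2), (2, 4), (3, 4)]
        pg = planarize(_graph(pts, edges))
        assert len(fundamental_cycles(pg)) == len(pg.edges) - len(pg.coords) + 1 == 3

    def test_random_count_per_component(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 30, size=(12, 2))
        edges = {tuple(sorted(rng.choice(12, 2, replace=False))) for _ in range(16)}
        pg = planarize(_graph(pts, {(int(a), int(b)) for a, b in edges}))
        G = pg.to_networkx()
        want = sum(
            G.subgraph(c).number_of_edges() - len(c) + 1
            for c in nx.connected_components(G)
        )
        assert len(fundamental_cycles(pg)) == want


class TestEnclosureClasses:
    def _ring_walk(self, r, n=8, center=(0.0, 0.0)):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack(
            [center[0] + r * np.cos(th), center[1] + r * np.sin(th)]
        )
        return pts

    def test_single_ring(self):
        ring = self._ring_walk(10)
        pg_coords = {k: ring[k] for k in range(8)}
        from isletrings.geometric import PlanarGraph

        pg = PlanarGraph(coords=pg_coords, edges=set())
        cycles = [list(range(8)) + [0]]
        markers = {100: np.array([1.0, 0.5]), 101: np.array([-2.0, 1.0]), 102: np.array([0.0, -3.0])}
        classes = enclosure_classes(markers, cycles, pg)
        assert len(classes) == 1
        assert classes[0]["members"] == frozenset({100, 101, 102})

    def test_no_marker_inside(self):
        ring = self._ring_walk(5)
        from isletrings.geometric import PlanarGraph

        pg = PlanarGraph(coords={k: ring[k] for k in range(8)}, edges=set())
        classes = enclosure_classes(
            {7: np.array([30.0, 30.0])}, [list(range(8)) + [0]], pg
        )
        assert classes == []

    def test_nested_rings(self):
        outer = self._ring_walk(10)
        inner = self._ring_walk(4)
        coords = {k: outer[k] for k in range(8)}
        coords.update({8 + k: inner[k] for k in range(8)})
        from isletrings.geometric import PlanarGraph

        pg = PlanarGraph(coords=coords, edges=set())
        cycles = [list(range(8)) + [0], list(range(8, 16)) + [8]]
        markers = {
            50: np.array([0.5, 0.5]),  # inside both
            51: np.array([0.0, 1.0]),  # inside both
            52: np.array([0.0, 7.0]),  # outer only
        }
        classes = enclosure_classes(markers, cycles, pg)
        got = {cls["members"] for cls in classes}
        assert got == {frozenset({50, 51}), frozenset({52})}


class TestMinimalEnclosingCycle:
    def test_diamond_ring(self):
        pts = [(10, 0), (0, 10), (-10, 0), (0, -10)]
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
        pg = planarize(_graph(pts, edges))
        gc = minimal_enclosing_cycle(
            frozenset({99}), {99: np.array([0.0, 0.0])}, pg
        )
        assert gc is not None
        assert gc.walk[0] == gc.walk[-1]
        assert set(gc.walk) == {0, 1, 2, 3}

    def test_octagon_with_chord_keeps_full_ring(self):
        th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = [(10 * np.cos(t), 10 * np.sin(t)) for t in th]
        edges = [(k, (k + 1) % 8) for k in range(8)] + [(1, 6)]  # one chord
        pg = planarize(_graph(pts, edges))
        # markers on opposite sides of the chord from vertex 1 to vertex 6
        markers = {
            200: np.array([0.0, 4.0]),
            201: np.array([6.0, 0.0]),
        }
        gc = minimal_enclosing_cycle(frozenset({200, 201}), markers, pg)
        assert gc is not None
        poly = gc.polygon(pg.coords)
        for m in markers.values():
            assert winding_number(m, poly) != 0
        assert set(range(8)) <= set(gc.walk)

    def test_dead_end_spur_retries_next_pair(self):
        th = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = [(10 * np.cos(t), 10 * np.sin(t)) for t in th]
        pts.append((1.0, 0.5))  # spur vertex, closest to the marker
        edges = [(k, (k + 1) % 6) for k in range(6)] + [(6, 0)]
        pg = planarize(_graph(pts, edges))
        gc = minimal_enclosing_cycle(
            frozenset({77}), {77: np.array([0.2, 0.1])}, pg
        )
        assert gc is not None
        poly = gc.polygon(pg.coords)
        assert winding_number(np.array([0.2, 0.1]), poly) != 0

    def test_no_cycle_result_distinguishable(self):
        # path graph cannot enclose anything
        pts = [(0, 0), (10, 0), (20, 0)]
        pg = planarize(_graph(pts, [(0, 1), (1, 2)]))
        got = minimal_enclosing_cycle(frozenset({5}), {5: np.array([5.0, 1.0])}, pg)
        assert got is None


class TestPipelineInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_ring_islets_single_ns_component_enclosed(self, seed):
        islet = gen_ring_islet(seed=seed)
        sgraph = build_class_graph(islet, "alphadelta")
        m_ids, m_coords = islet.class_arrays("beta")
        cycles, classes, pg = find_geometric_cycles(sgraph, m_ids, m_coords)
        assert len(cycles) >= 1
        adjacency = {tuple(sorted(e)) for e in pg.edges}
        for gc in cycles:
            assert gc.walk[0] == gc.walk[-1]
            for a, b in zip(gc.walk, gc.walk[1:]):
                assert tuple(sorted((a, b))) in adjacency
            poly = gc.polygon(pg.coords)
            for m, c in zip(m_ids, m_coords):
                if m in gc.enclosed:
                    assert winding_number(c, poly) != 0
        # all core cells fall in one enclosure class
        assert any(cls["members"] == frozenset(m_ids) for cls in classes)
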