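"""Shared fixtures and independent oracles.

Reduction invariant checking (R = D.V over GF(2), unit upper-triangular V,
unique pivots) is switched on for every reduction performed anywhere in the
suite.  The oracles here are deliberately implemented from first principles
(brute-force ranks, ray casting, pair counting) so they share no code with
the library paths they check.
"""

import numpy as np
import pytest

import isletrings.homology as homology


@pytest.fixture(autouse=True, scope="session")
def _validate_all_reductions():
    homology.VALIDATE = True
    yield
    homology.VALIDATE = False


# ---------------------------------------------------------------------------
# GF(2) rank oracle (independent of the library's reduction)
# ---------------------------------------------------------------------------

def gf2_rank(columns):
    """Rank of a GF(2) matrix given as int bit-columns, by plain elimination."""
    basis = {}
    rank = 0
    for col in columns:
        c = int(col)
        while c:
            p = c.bit_length() - 1
            if p in basis:
                c ^= basis[p]
            else:
                basis[p] = c
                rank += 1
                break
    return rank


def oracle_pairs_dim1(filt):
    """Dimension-1 persistence pairs recomputed purely from GF(2) ranks of
    boundary-matrix submatrices at every filtration step.

    A triangle column j kills iff it raises the rank of the triangle
    boundary matrix; by the pairing-uniqueness theorem its pivot row is the
    largest i such that the lower-left submatrix (rows >= i, cols <= j)
    still gains rank at column j (binary search over a monotone 0/1
    function of i).  Edge creators are edge columns that do not raise the
    rank of the vertex boundary matrix; creators never killed are undying.
    Returns (finite pairs as (birth, death) list, undying births).
    """
    from isletrings.homology import (
        _edge_boundary_columns,
        _triangle_boundary_columns,
    )

    De, _ = _edge_boundary_columns(filt)
    Dt, _ = _triangle_boundary_columns(filt)

    creators = []
    rank = 0
    for j in range(len(De)):
        new_rank = gf2_rank(De[: j + 1])
        if new_rank == rank:
            creators.append(j)
        rank = new_rank

    def gain(i, j):
        # does column j still raise the rank of the rows>=i submatrix?
        cols_prev = [c >> i for c in Dt[:j]]
        cols_now = [c >> i for c in Dt[: j + 1]]
        return gf2_rank(cols_now) - gf2_rank(cols_prev)

    finite = []
    killed_rows = set()
    n_rows = len(De)
    rank = 0
    for j in range(len(Dt)):
        new_rank = gf2_rank(Dt[: j + 1])
        if new_rank == rank:
            continue
        rank = new_rank
        # largest i with gain(i, j) == 1 (monotone nonincreasing in i)
        lo, hi = 0, n_rows - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if gain(mid, j) == 1:
                lo = mid
            else:
                hi = mid - 1
        killed_rows.add(lo)
        finite.append((filt.edge_scales[lo], filt.triangle_scales[j]))
    undying = [filt.edge_scales[i] for i in creators if i not in killed_rows]
    return finite, undying


# ---------------------------------------------------------------------------
# geometry oracles
# ---------------------------------------------------------------------------

def ray_casting_inside(point, polygon):
    """Even-odd horizontal ray-casting point-in-polygon (closed ring)."""
    x, y = float(point[0]), float(point[1])
    poly = np.asarray(polygon, dtype=float)
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    inside = False
    for k in range(len(poly) - 1):
        (x1, y1), (x2, y2) = poly[k], poly[k + 1]
        if (y1 > y) != (y2 > y):
            xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xc > x:
                inside = not inside
    return inside


def segments_properly_cross(p1, p2, p3, p4):
    """Orientation-based proper segment crossing test (endpoints excluded)."""

    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 * o2 < 0 and o3 * o4 < 0


def random_simple_polygon(rng, n_vertices=8, radius=10.0):
    """Star-shaped (hence simple) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3 * radius, radius, n_vertices)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    return np.vstack([pts, pts[0]])
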