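"""Islet periphery estimation and cycle position morphometry.

The periphery of a 2D section can be non-convex, so it is estimated as an
alpha shape: Delaunay triangles with circumradius below 1/shrink_factor are
kept and unioned.  Starting from shrink factor 1/max(tau_beta, tau_alphadelta),
the factor is halved until the shape is a single polygon; shrink factor 0
is the convex hull, so the loop always terminates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import LinearRing, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .datamodel import DegenerateInputError
from .geometric import winding_number


@dataclass
class PeripheryShape:
    """Single simple closed ring approximating the islet outline."""

    polygon: np.ndarray  # closed ring, first == last vertex
    shrink_factor_used: float
    area: float
    centroid: np.ndarray

    @property
    def ring(self) -> LinearRing:
        return LinearRing(self.polygon)


def _circumradius(a, b, c) -> float:
    la, lb, lc = (
        np.linalg.norm(b - c),
        np.linalg.norm(a - c),
        np.linalg.norm(a - b),
    )
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return np.inf
    return la * lb * lc / (2 * area2)


def alpha_shape(coords: np.ndarray, shrink_factor: float):
    """Union of Delaunay triangles with circumradius < 1/shrink_factor.

    Shrink factor 0 (or negative) returns the convex hull.  The result may
    be a Polygon, a MultiPolygon, or empty.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if shrink_factor <= 0:
        return MultiPoint([tuple(p) for p in coords]).convex_hull
    try:
        tri = Delaunay(coords)
    except QhullError as e:
        raise DegenerateInputError(f"degenerate point set: {e}") from e
    limit = 1.0 / shrink_factor
    polys = []
    for simplex in tri.simplices:
        a, b, c = coords[simplex]
        if _circumradius(a, b, c) < limit:
            polys.append(Polygon([a, b, c]))
    return unary_union(polys)


def estimate_periphery(
    coords: np.ndarray, tau_beta: float, tau_alphadelta: float
) -> PeripheryShape:
    """Adaptive alpha-shape periphery of all islet cells.

    The initial shrink factor is the multiplicative inverse of the larger of
    the two neighborhood radii; while the alpha shape is not a single
    polygon, the factor is halved.  Returns the single-polygon shape at the
    largest shrink factor reached.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 3:
        raise DegenerateInputError("periphery needs at least three cells")
    sf = 1.0 / max(tau_beta, tau_alphadelta)
    for _ in range(64):
        shape = alpha_shape(coords, sf)
        if isinstance(shape, Polygon) and not shape.is_empty and shape.area > 0:
            break
        sf = sf / 2.0
    else:
        sf = 0.0
        shape = alpha_shape(coords, sf)
    if not isinstance(shape, Polygon) or shape.area == 0:
        raise DegenerateInputError("could not form a polygonal periphery")
    ring = np.asarray(shape.exterior.coords, dtype=float)
    centroid = np.asarray(shape.exterior.centroid.coords[0], dtype=float)
    return PeripheryShape(
        polygon=ring,
        shrink_factor_used=sf,
        area=float(shape.area),
        centroid=centroid,
    )


def _as_ring(poly: np.ndarray) -> LinearRing:
    poly = np.atleast_2d(np.asarray(poly, dtype=float))
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    return LinearRing(poly)


def min_distance_to_periphery(cycle_polygon: np.ndarray, periphery: PeripheryShape) -> float:
    """Minimum Euclidean distance between the cycle boundary and the
    periphery boundary; 0 when they touch or cross (boundaries compared, so
    a cycle nested inside the islet still gets a positive distance)."""
    return float(_as_ring(cycle_polygon).distance(periphery.ring))


def min_distance_to_center(cycle_polygon: np.ndarray, center: np.ndarray) -> float:
    """Minimum distance from the islet center (periphery centroid) to the
    cycle boundary; 0 when the center lies on it."""
    return float(Point(np.asarray(center, dtype=float)).distance(_as_ring(cycle_polygon)))


def contains_center(cycle_polygon: np.ndarray, center: np.ndarray) -> bool:
    """Winding-number containment of the islet center in the cycle."""
    poly = np.atleast_2d(np.asarray(cycle_polygon, dtype=float))
    return winding_number(np.asarray(center, dtype=float), poly) != 0


def alpha_shape_area(periphery: PeripheryShape | np.ndarray) -> float:
    """Polygon area by the shoelace formula (the islet's estimated area)."""
    poly = periphery.polygon if isinstance(periphery, PeripheryShape) else periphery
    poly = np.atleast_2d(np.asarray(poly, dtype=float))
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    x, y = poly[:-1, 0], poly[:-1, 1]
    xs, ys = poly[1:, 0], poly[1:, 1]
    return float(abs(np.sum(x * ys - xs * y)) / 2.0)
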