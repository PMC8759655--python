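"""Confinement-region geometry.

Adhesive micropatterns confine migrating cells to a region of the substrate.
This module represents those regions (disks, rectangles, polygons, and a
region minus a hole) and answers the geometric queries the simulator and the
boundary analyses need: containment, signed distance to the boundary, and the
boundary tangent together with its curvature class.

Conventions
-----------
* Coordinates are continuous micrometres in a right-handed x-y plane.
* Regions are closed: a point exactly on the boundary counts as inside,
  because cells migrating along the boundary must be at legal positions.
* The boundary tangent is oriented counter-clockwise with respect to the
  region interior (interior on the left of the tangent).
* Boundary curvature classes: ``linear`` for straight segments;
  ``concave_arc`` when the centre of curvature lies inside the region (the
  rim of a disk seen from inside); ``convex_arc`` when it lies outside (the
  rim of a subtracted hole).
* Corners of rectangles and polygons have no tangent; querying one raises
  :class:`CornerPointError` so angle analyses can exclude them.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "BoundaryClass",
    "Point2D",
    "Region",
    "Disk",
    "Rectangle",
    "PolygonRegion",
    "Difference",
    "NotOnBoundaryError",
    "CornerPointError",
    "region_from_dict",
    "region_to_dict",
]

#: Default tolerance (um) for deciding that a point lies on the boundary.
BOUNDARY_TOL = 1e-6


class BoundaryClass(str, Enum):
    """Curvature class of a boundary point."""

    LINEAR = "linear"
    CONCAVE_ARC = "concave_arc"
    CONVEX_ARC = "convex_arc"


class NotOnBoundaryError(ValueError):
    """Raised when a tangent is requested at a point away from the boundary."""


class CornerPointError(ValueError):
    """Raised at corner points, where the tangent is undefined."""


@dataclass(frozen=True)
class Point2D:
    """A position in the substrate plane, in micrometres."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")

    def __iter__(self):
        return iter((self.x, self.y))


def _as_xy(p) -> np.ndarray:
    a = np.asarray(tuple(p) if isinstance(p, Point2D) else p, dtype=float)
    if a.shape != (2,):
        raise ValueError(f"expected a 2-D point, got shape {a.shape}")
    return a


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a vector by +90 degrees (counter-clockwise)."""
    return np.array([-v[1], v[0]])


class Region(ABC):
    """A closed confinement region in the plane."""

    kind: str

    # -- scalar queries -------------------------------------------------

    def contains(self, p) -> bool:
        """True iff ``p`` lies in the closed region (boundary included)."""
        return bool(self.signed_distance(_as_xy(p)) >= -BOUNDARY_TOL)

    @abstractmethod
    def signed_distance(self, p) -> float:
        """Signed Euclidean distance to the boundary: >0 inside, <0 outside."""

    @abstractmethod
    def nearest_boundary_point(self, p) -> np.ndarray:
        """The boundary point closest to ``p``."""

    @abstractmethod
    def boundary_tangent_and_class(
        self, p, tol: float = BOUNDARY_TOL
    ) -> tuple[np.ndarray, BoundaryClass]:
        """Unit tangent (CCW w.r.t. interior) and curvature class at ``p``.

        ``p`` must lie within ``tol`` of the boundary, and not at a corner.
        """

    def inward_normal(self, p_on_boundary) -> np.ndarray:
        """Unit normal at a boundary point, pointing into the region."""
        t, _ = self.boundary_tangent_and_class(p_on_boundary, tol=np.inf)
        # interior on the left of the CCW tangent
        return _rot90(t)

    # -- vectorised queries (used by the simulator) ---------------------

    def signed_distance_many(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.array([self.signed_distance(p) for p in pts])

    def contains_many(self, pts: np.ndarray) -> np.ndarray:
        return self.signed_distance_many(pts) >= -BOUNDARY_TOL

    def nearest_boundary_many(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.array([self.nearest_boundary_point(p) for p in pts])

    # -- misc ------------------------------------------------------------

    @abstractmethod
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the region."""

    @abstractmethod
    def area(self) -> float:
        """Region area in um^2."""

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random points inside the region (rejection sampling)."""
        xmin, ymin, xmax, ymax = self.bounds()
        out = np.empty((n, 2))
        filled = 0
        for _ in range(10_000):
            m = max(4 * (n - filled), 16)
            cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(m, 2))
            ok = cand[self.contains_many(cand)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
            if filled == n:
                return out
        raise RuntimeError("rejection sampling failed; region area may be tiny")


class Disk(Region):
    """A circular adhesive island (e.g. the 100-um-diameter pattern)."""

    kind = "disk"

    def __init__(self, center=(0.0, 0.0), radius: float = 50.0):
        if radius <= 0:
            raise ValueError("disk radius must be positive")
        self.center = _as_xy(center)
        self.radius = float(radius)

    def signed_distance(self, p) -> float:
        return self.radius - float(np.linalg.norm(_as_xy(p) - self.center))

    def signed_distance_many(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return self.radius - np.linalg.norm(pts - self.center, axis=1)

    def nearest_boundary_point(self, p) -> np.ndarray:
        p = _as_xy(p)
        d = p - self.center
        r = np.linalg.norm(d)
        if r == 0.0:  # degenerate: any boundary point is nearest; pick +x
            return self.center + np.array([self.radius, 0.0])
        return self.center + d * (self.radius / r)

    def nearest_boundary_many(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = pts - self.center
        r = np.linalg.norm(d, axis=1, keepdims=True)
        r = np.where(r == 0.0, 1.0, r)
        return self.center + d * (self.radius / r)

    def boundary_tangent_and_class(self, p, tol=BOUNDARY_TOL):
        p = _as_xy(p)
        if abs(self.signed_distance(p)) > tol:
            raise NotOnBoundaryError(f"{p} is not on the disk boundary")
        outward = p - self.center
        outward = outward / np.linalg.norm(outward)
        return _rot90(outward), BoundaryClass.CONCAVE_ARC

    def bounds(self):
        cx, cy = self.center
        r = self.radius
        return (cx - r, cy - r, cx + r, cy + r)

    def area(self) -> float:
        return math.pi * self.radius**2


class Rectangle(Region):
    """An axis-aligned rectangular adhesive area (e.g. a 15 x 15 um lattice cell)."""

    kind = "rectangle"

    def __init__(self, corner=(0.0, 0.0), width: float = 15.0, height: float = 15.0):
        if width <= 0 or height <= 0:
            raise ValueError("rectangle extents must be positive")
        self.corner = _as_xy(corner)
        self.width = float(width)
        self.height = float(height)

    @property
    def _hi(self) -> np.ndarray:
        return self.corner + (self.width, self.height)

    def signed_distance(self, p) -> float:
        p = _as_xy(p)
        lo, hi = self.corner, self._hi
        # distance to the four edge lines, inside-positive box SDF
        d = np.minimum(p - lo, hi - p)
        inside_d = min(d)
        if inside_d >= 0:
            return float(inside_d)
        outside = np.maximum(np.maximum(lo - p, p - hi), 0.0)
        return -float(np.linalg.norm(outside))

    def signed_distance_many(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lo, hi = self.corner, self._hi
        d = np.minimum(pts - lo, hi - pts)
        inside_d = d.min(axis=1)
        outside = np.maximum(np.maximum(lo - pts, pts - hi), 0.0)
        out_d = np.linalg.norm(outside, axis=1)
        return np.where(inside_d >= 0, inside_d, -out_d)

    def nearest_boundary_point(self, p) -> np.ndarray:
        p = _as_xy(p)
        lo, hi = self.corner, self._hi
        q = np.clip(p, lo, hi)
        if np.any(q != p):  # outside: clamp is the nearest boundary point
            return q
        # inside: push to the closest edge
        dists = np.array([p[0] - lo[0], hi[0] - p[0], p[1] - lo[1], hi[1] - p[1]])
        i = int(np.argmin(dists))
        q = p.copy()
        q[0 if i < 2 else 1] = (lo, hi)[i % 2][0 if i < 2 else 1]
        return q

    def boundary_tangent_and_class(self, p, tol=BOUNDARY_TOL):
        p = _as_xy(p)
        if abs(self.signed_distance(p)) > tol:
            raise NotOnBoundaryError(f"{p} is not on the rectangle boundary")
        lo, hi = self.corner, self._hi
        # nearest edge decides the tangent; a corner is ambiguous between two
        edge_d = np.abs([p[0] - lo[0], p[0] - hi[0], p[1] - lo[1], p[1] - hi[1]])
        order = np.argsort(edge_d)
        corner_tol = max(BOUNDARY_TOL, min(tol, 1e-3))
        if edge_d[order[1]] - edge_d[order[0]] <= corner_tol and (
            edge_d[order[1]] <= corner_tol
        ):
            raise CornerPointError(f"{p} is a rectangle corner; tangent undefined")
        # CCW orientation: interior on the left of the tangent
        tangents = {
            0: np.array([0.0, -1.0]),  # left edge
            1: np.array([0.0, 1.0]),  # right edge
            2: np.array([1.0, 0.0]),  # bottom edge
            3: np.array([-1.0, 0.0]),  # top edge
        }
        return tangents[int(order[0])], BoundaryClass.LINEAR

    def bounds(self):
        lo, hi = self.corner, self._hi
        return (lo[0], lo[1], hi[0], hi[1])

    def area(self) -> float:
        return self.width * self.height


class PolygonRegion(Region):
    """A simple polygonal adhesive area; boundary segments are all linear."""

    kind = "polygon"

    def __init__(self, vertices: Sequence):
        verts = np.asarray([_as_xy(v) for v in vertices], dtype=float)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")
        # normalise to CCW vertex order so edge tangents are CCW
        if poly.exterior.is_ccw:
            self.vertices = verts
        else:
            self.vertices = verts[::-1]
        self._poly = _ShapelyPolygon(self.vertices)

    def signed_distance(self, p) -> float:
        sp = _ShapelyPoint(_as_xy(p))
        d = self._poly.exterior.distance(sp)
        return d if self._poly.covers(sp) else -d

    def nearest_boundary_point(self, p) -> np.ndarray:
        sp = _ShapelyPoint(_as_xy(p))
        q = self._poly.exterior.interpolate(self._poly.exterior.project(sp))
        return np.array([q.x, q.y])

    def boundary_tangent_and_class(self, p, tol=BOUNDARY_TOL):
        p = _as_xy(p)
        if abs(self.signed_distance(p)) > tol:
            raise NotOnBoundaryError(f"{p} is not on the polygon boundary")
        verts = self.vertices
        n = len(verts)
        corner_tol = max(BOUNDARY_TOL, min(tol, 1e-3))
        if any(np.linalg.norm(p - v) <= corner_tol for v in verts):
            raise CornerPointError(f"{p} is a polygon vertex; tangent undefined")
        best, best_d = None, np.inf
        for i in range(n):
            a, b = verts[i], verts[(i + 1) % n]
            ab = b - a
            s = float(np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0))
            d = float(np.linalg.norm(p - (a + s * ab)))
            if d < best_d:
                best_d, best = d, ab
        t = best / np.linalg.norm(best)
        return t, BoundaryClass.LINEAR

    def bounds(self):
        return self._poly.bounds

    def area(self) -> float:
        return self._poly.area


class Difference(Region):
    """An outer region minus a hole, e.g. the area between a square and a
    circle inside the square. The hole's rim is seen from outside the hole,
    so its arc class flips (a disk hole presents a convex arc)."""

    kind = "difference"

    def __init__(self, outer: Region, hole: Region):
        self.outer = outer
        self.hole = hole
        # sanity: hole centroid must lie inside the outer region
        xmin, ymin, xmax, ymax = hole.bounds()
        c = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
        if not outer.contains(c):
            raise ValueError("subtracted region must lie inside the outer region")

    def signed_distance(self, p) -> float:
        return min(self.outer.signed_distance(p), -self.hole.signed_distance(p))

    def signed_distance_many(self, pts) -> np.ndarray:
        return np.minimum(
            self.outer.signed_distance_many(pts),
            -self.hole.signed_distance_many(pts),
        )

    def nearest_boundary_point(self, p) -> np.ndarray:
        p = _as_xy(p)
        q_out = self.outer.nearest_boundary_point(p)
        q_hole = self.hole.nearest_boundary_point(p)
        if np.linalg.norm(p - q_out) <= np.linalg.norm(p - q_hole):
            return q_out
        return q_hole

    def boundary_tangent_and_class(self, p, tol=BOUNDARY_TOL):
        p = _as_xy(p)
        if abs(self.signed_distance(p)) > tol:
            raise NotOnBoundaryError(f"{p} is not on the region boundary")
        if abs(self.outer.signed_distance(p)) <= abs(self.hole.signed_distance(p)):
            return self.outer.boundary_tangent_and_class(p, tol=tol)
        t, cls = self.hole.boundary_tangent_and_class(p, tol=tol)
        flip = {
            BoundaryClass.CONCAVE_ARC: BoundaryClass.CONVEX_ARC,
            BoundaryClass.CONVEX_ARC: BoundaryClass.CONCAVE_ARC,
            BoundaryClass.LINEAR: BoundaryClass.LINEAR,
        }
        return -t, flip[cls]  # orientation reverses on the hole rim

    def bounds(self):
        return self.outer.bounds()

    def area(self) -> float:
        return self.outer.area() - self.hole.area()


# ---------------------------------------------------------------------------
# Config (de)serialisation. All lengths are micrometres, stated in key names.
# ---------------------------------------------------------------------------

def region_from_dict(d: dict) -> Region:
    """Build a region from a config mapping.

    Schema (one example per kind)::

        {kind: disk, center_um: [0, 0], radius_um: 50}
        {kind: rectangle, corner_um: [0, 0], width_um: 15, height_um: 15}
        {kind: polygon, vertices_um: [[0, 0], [30, 0], [15, 25]]}
        {kind: difference,
         outer: {kind: rectangle, corner_um: [-300, -300],
                 width_um: 600, height_um: 600},
         hole: {kind: disk, center_um: [0, 0], radius_um: 100}}
    """
    d = dict(d)
    kind = d.pop("kind", None)
    builders = {
        "disk": lambda: Disk(d.pop("center_um", (0.0, 0.0)), d.pop("radius_um")),
        "rectangle": lambda: Rectangle(
            d.pop("corner_um", (0.0, 0.0)), d.pop("width_um"), d.pop("height_um")
        ),
        "polygon": lambda: PolygonRegion(d.pop("vertices_um")),
        "difference": lambda: Difference(
            region_from_dict(d.pop("outer")), region_from_dict(d.pop("hole"))
        ),
    }
    if kind not in builders:
        raise ValueError(f"unknown region kind: {kind!r}")
    region = builders[kind]()
    if d:
        raise ValueError(f"unknown region config keys: {sorted(d)}")
    return region


def region_to_dict(region: Region) -> dict:
    if isinstance(region, Disk):
        return {
            "kind": "disk",
            "center_um": [float(c) for c in region.center],
            "radius_um": region.radius,
        }
    if isinstance(region, Rectangle):
        return {
            "kind": "rectangle",
            "corner_um": [float(c) for c in region.corner],
            "width_um": region.width,
            "height_um": region.height,
        }
    if isinstance(region, PolygonRegion):
        return {
            "kind": "polygon",
            "vertices_um": [[float(x), float(y)] for x, y in region.vertices],
        }
    if isinstance(region, Difference):
        return {
            "kind": "difference",
            "outer": region_to_dict(region.outer),
            "hole": region_to_dict(region.hole),
        }
    raise TypeError(f"cannot serialise region of type {type(region)!r}")
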