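"""Planar worlds with binary habitability.

Geometry is purely polygonal on an abstract planar landscape measured in
"map units": population ranges are simple polygons, circles are regular
polygons (64 vertices by default), and each point of the world either is
or is not habitable.  There is no notion of a coordinate reference system.

All heavy lifting is delegated to :mod:`shapely`; this module fixes the
conventions (closed-set membership, clipping to the world, rejection
sampling) used by the rest of the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry import MultiPolygon as _ShapelyMultiPolygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = [
    "Point",
    "Region",
    "World",
    "make_world",
    "point_in_region",
    "sample_point_uniform",
    "translate_region",
    "buffer_region",
    "circle_region",
]

#: number of vertices used to discretize circles
CIRCLE_VERTICES = 64

#: consecutive rejection-sampling failures before giving up
MAX_REJECTIONS = 100_000


class Point(NamedTuple):
    """A location on the landscape, in map units."""

    x: float
    y: float


def _require_finite(p: Point) -> Point:
    if not (math.isfinite(p[0]) and math.isfinite(p[1])):
        raise ValueError(f"point coordinates must be finite, got {p}")
    return Point(float(p[0]), float(p[1]))


@dataclass(frozen=True)
class Region:
    """A named region of the landscape.

    The canonical case is a simple closed polygon given counter-clockwise;
    clipping against the world or against habitable areas may however leave
    a multi-part geometry, so internally any polygonal shapely geometry is
    accepted.
    """

    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        geom = self.geometry
        if not isinstance(geom, (_ShapelyPolygon, _ShapelyMultiPolygon)):
            raise ValueError(
                f"region {self.name!r}: geometry must be polygonal, got {geom.geom_type}"
            )
        if not geom.is_valid:
            raise ValueError(f"region {self.name!r}: polygon is invalid (self-intersecting?)")
        if geom.area <= 0:
            raise ValueError(f"region {self.name!r}: area must be positive")
        # normalize ring order/orientation for reproducible WKT output
        object.__setattr__(self, "geometry", shapely.normalize(geom))

    @classmethod
    def from_vertices(cls, name: str, vertices: Sequence[Point]) -> "Region":
        """Build a region from a sequence of boundary points (implicitly closed)."""
        verts = [_require_finite(Point(*v)) for v in vertices]
        if len(verts) < 3:
            raise ValueError(f"region {name!r}: need at least 3 vertices")
        poly = _ShapelyPolygon(verts)
        return cls(name, poly)

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def boundary(self) -> list[Point]:
        """Exterior vertices of the (largest) polygon part, without the closing point."""
        geom = self.geometry
        if isinstance(geom, _ShapelyMultiPolygon):
            geom = max(geom.geoms, key=lambda g: g.area)
        coords = list(geom.exterior.coords)[:-1]
        return [Point(x, y) for x, y in coords]

    def to_wkt(self) -> str:
        # full precision: bundle round-trips must reproduce geometry exactly
        return shapely.to_wkt(self.geometry, rounding_precision=-1)


def circle_region(
    name: str, center: Point, radius: float, vertices: int = CIRCLE_VERTICES
) -> Region:
    """A circle discretized as a regular ``vertices``-gon.

    With 64 vertices the polygonal area underestimates the true disk area by
    less than 0.2%, which is well within the tolerances used elsewhere.
    """
    if radius <= 0:
        raise ValueError("circle radius must be positive")
    cx, cy = _require_finite(Point(*center))
    angles = 2.0 * math.pi * np.arange(vertices) / vertices
    pts = [Point(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles]
    return Region.from_vertices(name, pts)


@dataclass(frozen=True)
class World:
    """Rectangular planar world with a binary-habitability mask.

    ``habitable`` empty means the whole extent is habitable.
    """

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    habitable: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = (float(v) for v in self.extent)
        if not all(math.isfinite(v) for v in (xmin, ymin, xmax, ymax)):
            raise ValueError("world extent must be finite")
        if xmax <= xmin or ymax <= ymin:
            raise ValueError(f"degenerate world extent {self.extent}")
        object.__setattr__(self, "extent", (xmin, ymin, xmax, ymax))

    @property
    def extent_polygon(self) -> _ShapelyPolygon:
        xmin, ymin, xmax, ymax = self.extent
        return shapely.box(xmin, ymin, xmax, ymax)

    @property
    def habitable_geometry(self) -> BaseGeometry:
        """Union of habitable regions, or the full extent when none are given."""
        if not self.habitable:
            return self.extent_polygon
        return unary_union([r.geometry for r in self.habitable])

    @property
    def diagonal(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return math.hypot(xmax - xmin, ymax - ymin)

    def clip(self, geometry: BaseGeometry) -> BaseGeometry:
        """Intersect a geometry with the habitable part of the world."""
        return geometry.intersection(self.habitable_geometry)


def make_world(
    extent: tuple[float, float, float, float],
    habitable_regions: Sequence[Region] = (),
) -> World:
    """Create a planar world, clipping habitable regions to the extent."""
    world = World(extent)  # validates the extent
    clipped: list[Region] = []
    for region in habitable_regions:
        inter = region.geometry.intersection(world.extent_polygon)
        if inter.is_empty or inter.area <= 0:
            raise ValueError(
                f"habitable region {region.name!r} lies entirely outside the world extent"
            )
        clipped.append(Region(region.name, inter))
    return World(world.extent, tuple(clipped))


def point_in_region(p: Point, r: Region) -> bool:
    """Closed-set membership test: boundary points count as inside."""
    return bool(shapely.intersects_xy(r.geometry, p[0], p[1]))


def points_in_geometry(geometry: BaseGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized closed-set membership for many points at once."""
    return shapely.intersects_xy(geometry, x, y)


def sample_point_uniform(
    world: World, r: Region, rng: np.random.Generator, size: int | None = None
):
    """Uniform point(s) on ``r`` intersected with the habitable world.

    Uses bounding-box rejection sampling; boundary points are acceptable
    (closed-set convention), which guarantees termination even for regions
    that have been clipped down to thin slivers.
    """
    target = world.clip(r.geometry)
    if target.is_empty or target.area <= 0:
        raise ValueError(
            f"region {r.name!r} has no habitable area to sample from"
        )
    n = 1 if size is None else int(size)
    xmin, ymin, xmax, ymax = target.bounds
    out_x = np.empty(n)
    out_y = np.empty(n)
    filled = 0
    rejections = 0
    while filled < n:
        m = max(64, 2 * (n - filled))
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        ok = shapely.intersects_xy(target, xs, ys)
        k = int(ok.sum())
        take = min(k, n - filled)
        if take:
            out_x[filled : filled + take] = xs[ok][:take]
            out_y[filled : filled + take] = ys[ok][:take]
            filled += take
        if k == 0:
            rejections += m
            if rejections > MAX_REJECTIONS:
                raise RuntimeError(
                    f"rejection sampling failed {rejections} times in region "
                    f"{r.name!r}; geometry is likely degenerate"
                )
        else:
            rejections = 0
    if size is None:
        return Point(float(out_x[0]), float(out_y[0]))
    return np.column_stack([out_x, out_y])


def translate_region(r: Region, dx: float, dy: float) -> Region:
    """Shift every vertex by (dx, dy); area is preserved exactly."""
    if not (math.isfinite(dx) and math.isfinite(dy)):
        raise ValueError("translation offsets must be finite")
    return Region(r.name, shapely.affinity.translate(r.geometry, dx, dy))


def buffer_region(r: Region, d: float, world: World) -> Region:
    """Grow (d > 0) or shrink (d < 0) a region, clipped to the habitable world.

    A negative offset that collapses the region to zero area is an error.
    """
    if not math.isfinite(d):
        raise ValueError("buffer distance must be finite")
    grown = r.geometry.buffer(d) if d != 0 else r.geometry
    if grown.is_empty or grown.area <= 0:
        raise ValueError(
            f"negative buffer {d} collapses region {r.name!r} to zero area"
        )
    clipped = world.clip(grown).intersection(world.extent_polygon)
    if clipped.is_empty or clipped.area <= 0:
        raise ValueError(
            f"buffered region {r.name!r} has no habitable area left"
        )
    return Region(r.name, clipped)


# shapely.affinity is a submodule and must be imported explicitly
import shapely.affinity  # noqa: E402
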