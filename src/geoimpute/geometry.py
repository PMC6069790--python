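"""Planar geometry primitives.

All coordinates in this package are planar meters in an equal-area projected
frame (the kind of frame error distances are meaningful in, e.g. a state
Albers projection).  Nothing here does geodesic math; loaders validate a
units tag instead (see :mod:`geoimpute.io`).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, SamplingError

#: Default cap on rejection-sampling batches x batch size (total attempts).
DEFAULT_ATTEMPT_CAP = 10_000


def validate_polygon(polygon: BaseGeometry, *, context: str = "") -> None:
    """Raise :class:`GeometryError` unless ``polygon`` is a valid, simple,
    positive-area polygonal geometry."""
    where = f" ({context})" if context else ""
    if polygon is None or polygon.is_empty:
        raise GeometryError(f"empty geometry{where}")
    if not polygon.is_valid:
        raise GeometryError(
            f"invalid polygon{where}: {shapely.is_valid_reason(polygon)}"
        )
    if polygon.area <= 0.0:
        raise GeometryError(f"zero-area polygon{where}")


def polygon_centroid(polygon: BaseGeometry) -> tuple[float, float]:
    """Area-weighted geometric centroid as an (x, y) tuple.

    For a rectangle this is its center; in general it is the mean position
    of a uniform distribution over the polygon's interior.
    """
    validate_polygon(polygon)
    c = polygon.centroid
    return (c.x, c.y)


def random_point_in_polygon(
    polygon: BaseGeometry,
    rng: np.random.Generator,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
) -> tuple[float, float]:
    """A point uniform over the polygon's interior, via bounding-box
    rejection sampling.

    Deterministic given the generator state: candidates are drawn in fixed
    batches of 64 and consumed in order, so the same seeded ``rng`` always
    yields the same point.  Raises :class:`SamplingError` once the total
    number of candidate draws exceeds ``attempt_cap`` (pathologically thin
    polygons).
    """
    validate_polygon(polygon)
    minx, miny, maxx, maxy = polygon.bounds
    attempts = 0
    batch = 64
    while attempts < attempt_cap:
        k = min(batch, attempt_cap - attempts)
        xs = rng.uniform(minx, maxx, size=k)
        ys = rng.uniform(miny, maxy, size=k)
        hits = shapely.contains_xy(polygon, xs, ys)
        idx = np.flatnonzero(hits)
        if idx.size:
            i = idx[0]
            return (float(xs[i]), float(ys[i]))
        attempts += k
    raise SamplingError(
        f"rejection sampling exceeded {attempt_cap} attempts "
        f"(polygon area/bbox ratio {polygon.area / _bbox_area(polygon):.2e})"
    )


def _bbox_area(polygon: BaseGeometry) -> float:
    minx, miny, maxx, maxy = polygon.bounds
    return max((maxx - minx) * (maxy - miny), np.finfo(float).tiny)


def euclidean_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Planar Euclidean distance in meters."""
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def box(minx: float, miny: float, maxx: float, maxy: float) -> Polygon:
    """Axis-aligned rectangle (thin wrapper kept for import locality)."""
    return shapely.box(minx, miny, maxx, maxy)


def point(x: float, y: float) -> Point:
    return Point(x, y)
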