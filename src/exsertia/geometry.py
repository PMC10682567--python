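"""Great-circle geometry and the proportional range-marginality statistic.

A species' range is summarized by the arithmetic mean of its occurrence
coordinates (the range center) and the planar convex hull of those
coordinates (the range margin). A record's marginality is

    r = d_center / (d_center + d_margin)

where ``d_center`` is the great-circle distance from the record to the range
center and ``d_margin`` the minimum great-circle distance from the record to
the hull boundary. r runs from 0 at the range center to 1 on the margin.

The hull is computed planar on raw (longitude, latitude) pairs while both
distances are geodesic on a sphere — a deliberate hybrid matching the
standard geospatial toolchain for this statistic (planar `chull`-style hulls
with geodesic distance-to-polyline kernels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull as _QhullConvexHull
from scipy.spatial import QhullError

#: default sphere radius in meters (WGS84 equatorial radius, the convention
#: of the common geodesic-distance defaults)
EARTH_RADIUS = 6_378_137.0


class GeoPoint(NamedTuple):
    longitude: float
    latitude: float


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


@dataclass(slots=True)
class RangeModel:
    """Range center + convex hull for one species' occurrence cloud."""

    species: str
    center: GeoPoint
    hull: list[GeoPoint]  # counter-clockwise, no duplicate of the first vertex
    n_points: int


@dataclass(slots=True)
class MarginalityResult:
    d_center: float  # meters
    d_margin: float  # meters
    r: float  # unitless in [0, 1]


def great_circle_distance(a: GeoPoint, b: GeoPoint,
                          radius: float = EARTH_RADIUS) -> float:
    """Haversine distance between two points on a sphere, in meters.

    Symmetric, non-negative, and exactly zero for identical coordinates.
    """
    return float(_haversine(
        np.asarray(a[0], dtype=float), np.asarray(a[1], dtype=float),
        float(b[0]), float(b[1]), radius,
    ))


def _haversine(lon1, lat1, lon2, lat2, radius):
    """Vectorized haversine; first pair may be arrays."""
    lon1 = np.radians(lon1)
    lat1 = np.radians(lat1)
    lon2 = math.radians(lon2)
    lat2 = math.radians(lat2)
    s = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


def _to_unit_xyz(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _segment_distances(lons, lats, s1: GeoPoint, s2: GeoPoint,
                       radius: float) -> np.ndarray:
    """Min great-circle distance from each point to the arc s1–s2.

    Cross-track distance when the perpendicular foot falls within the arc,
    otherwise the distance to the nearer endpoint. Endpoint distances are
    always candidates, so a point coinciding with a vertex scores exactly 0.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    d1 = _haversine(lons, lats, s1[0], s1[1], radius)
    d2 = _haversine(lons, lats, s2[0], s2[1], radius)
    d_end = np.minimum(d1, d2)
    a = _to_unit_xyz(s1[0], s1[1])
    b = _to_unit_xyz(s2[0], s2[1])
    normal = np.cross(a, b)
    norm = np.linalg.norm(normal)
    if norm < 1e-15:  # coincident (or antipodal) endpoints: no unique arc
        return d_end
    normal = normal / norm
    p = _to_unit_xyz(lons, lats)
    # signed sine of the cross-track angle
    sin_xt = np.clip(p @ normal, -1.0, 1.0)
    d_xt = radius * np.arcsin(np.abs(sin_xt))
    # perpendicular foot on the great circle; inside-arc test via angles
    foot = p - sin_xt[..., None] * normal
    foot_norm = np.linalg.norm(foot, axis=-1)
    ok = foot_norm > 1e-15
    foot = np.where(ok[..., None], foot / np.where(ok, foot_norm, 1.0)[..., None], foot)
    arc = math.acos(float(np.clip(a @ b, -1.0, 1.0)))
    ang_a = np.arccos(np.clip(foot @ a, -1.0, 1.0))
    ang_b = np.arccos(np.clip(foot @ b, -1.0, 1.0))
    inside = ok & (ang_a <= arc) & (ang_b <= arc)
    return np.where(inside, np.minimum(d_xt, d_end), d_end)


def point_to_geodesic_segment(p: GeoPoint, s1: GeoPoint, s2: GeoPoint,
                              radius: float = EARTH_RADIUS) -> float:
    """Minimum great-circle distance from ``p`` to the arc from s1 to s2."""
    return float(_segment_distances(
        np.asarray(p[0], dtype=float), np.asarray(p[1], dtype=float),
        s1, s2, radius,
    ))


def convex_hull(points: Sequence[GeoPoint]) -> list[GeoPoint]:
    """Planar convex hull of raw (longitude, latitude) pairs.

    Returns hull vertices in counter-clockwise order without repeating the
    first vertex; collinear boundary points are excluded. Fewer than three
    distinct non-collinear points is a degenerate range.
    """
    coords = np.asarray([(p[0], p[1]) for p in points], dtype=float)
    if len(np.unique(coords, axis=0)) < 3:
        raise GeometryError("degenerate range: fewer than 3 distinct points")
    try:
        hull = _QhullConvexHull(coords)
    except QhullError as exc:
        raise GeometryError(f"degenerate range: {exc}") from exc
    return [GeoPoint(float(coords[i, 0]), float(coords[i, 1]))
            for i in hull.vertices]


def build_range_model(records, species: Optional[str] = None,
                      ) -> RangeModel:
    """Build the range model from every coordinate-bearing record.

    The center is the arithmetic mean of member longitudes and latitudes;
    the hull is the planar convex hull of the same points. The model is
    meant to be built from ALL records of the species that carry
    coordinates, before any trait-based filtering, so the inferred range
    reflects the full occurrence cloud.

    ``records`` may be OccurrenceRecord objects or (longitude, latitude)
    pairs. If ``species`` is given, records are restricted to it.
    """
    pts: list[GeoPoint] = []
    label = species or ""
    for item in records:
        if hasattr(item, "longitude") and hasattr(item, "species"):
            if species is not None and item.species != species:
                continue
            if item.longitude is None or item.latitude is None:
                continue
            pts.append(GeoPoint(item.longitude, item.latitude))
            label = label or item.species
        else:
            lon, lat = item
            pts.append(GeoPoint(float(lon), float(lat)))
    if len(pts) < 3:
        raise GeometryError(
            f"degenerate range for species {label!r}: "
            f"{len(pts)} coordinate-bearing records (need >= 3)"
        )
    lons = np.array([p.longitude for p in pts])
    lats = np.array([p.latitude for p in pts])
    if lons.max() - lons.min() > 180.0:
        raise GeometryError(
            f"species {label!r} longitudes span more than 180 degrees; "
            "antimeridian-wrapping ranges are not supported"
        )
    try:
        hull = convex_hull(pts)
    except GeometryError as exc:
        raise GeometryError(f"species {label!r}: {exc}") from exc
    center = GeoPoint(float(lons.mean()), float(lats.mean()))
    return RangeModel(species=label, center=center, hull=hull, n_points=len(pts))


def _hull_distances(lons, lats, model: RangeModel, radius: float) -> np.ndarray:
    """Min distance from each point to the hull boundary (all edges)."""
    edges = list(zip(model.hull, model.hull[1:] + model.hull[:1]))
    d = np.full(np.shape(np.asarray(lons, dtype=float)), np.inf)
    for s1, s2 in edges:
        d = np.minimum(d, _segment_distances(lons, lats, s1, s2, radius))
    return d


def marginality(p: GeoPoint, range_model: RangeModel,
                radius: float = EARTH_RADIUS) -> MarginalityResult:
    """Proportional range marginality of a point: 0 at center, 1 on margin.

    The boundary distance is unsigned: interior and exterior points both
    measure distance to the nearest hull edge.
    """
    d_center = great_circle_distance(p, range_model.center, radius)
    d_margin = float(_hull_distances(
        np.asarray(p[0], dtype=float), np.asarray(p[1], dtype=float),
        range_model, radius,
    ))
    if d_center == 0.0:
        if d_margin == 0.0:
            raise GeometryError(
                "undefined marginality: point coincides with both the range "
                "center and the hull boundary"
            )
        return MarginalityResult(0.0, d_margin, 0.0)
    return MarginalityResult(d_center, d_margin, d_center / (d_center + d_margin))


def marginality_many(lons, lats, range_model: RangeModel,
                     radius: float = EARTH_RADIUS,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized marginality: arrays of (d_center, d_margin, r).

    Points at the exact range center get r = 0; a point coinciding with
    both center and boundary raises (degenerate range).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    d_center = _haversine(lons, lats, range_model.center[0],
                          range_model.center[1], radius)
    d_margin = _hull_distances(lons, lats, range_model, radius)
    denom = d_center + d_margin
    if np.any(denom == 0.0):
        raise GeometryError("undefined marginality: center lies on the hull boundary")
    r = np.where(d_center == 0.0, 0.0, d_center / denom)
    return d_center, d_margin, r


def range_model_to_geojson(model: RangeModel) -> dict:
    """Hull polygon + center point as a GeoJSON FeatureCollection (WGS84)."""
    ring = [[v.longitude, v.latitude] for v in model.hull]
    ring.append(ring[0])
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"species": model.species, "role": "range_hull",
                               "n_points": model.n_points},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            },
            {
                "type": "Feature",
                "properties": {"species": model.species, "role": "range_center"},
                "geometry": {"type": "Point",
                             "coordinates": [model.center.longitude,
                                             model.center.latitude]},
            },
        ],
    }
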