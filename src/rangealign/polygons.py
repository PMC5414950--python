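"""Expert range polygons and their projection onto the grid.

Membership is decided by planar polygon-rectangle intersection in lon-lat
space (edges are straight in the equal-angle plane), matching data that are
natively published on an equal-angle grid. A cell is occupied iff the
intersection has strictly positive area; boundary-only contact is not
occupancy. Areas in km^2, by contrast, always use spherical weighting: a
lon-lat geometry is mapped through the cylindrical equal-area transform
(lambda, sin phi), under which planar area times R^2 is the exact spherical
area for any region bounded by meridian/parallel segments, and an excellent
approximation for short oblique segments (geometries are densified before
the transform to bound the error).

Antimeridian handling: any polygon is normalized by unioning its 360-degree
longitude translates clipped to the world box, so ranges crossing 180 (or
expressed on a 0-360 longitude convention) rasterize identically to their
wrapped equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.affinity import translate
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.base import BaseGeometry

from .grid import GridError, GridSpec
from .rasters import CoverageWeightRaster, PresenceRaster

__all__ = [
    "GeometryError",
    "RangePolygonSet",
    "normalize_geometry",
    "rasterize_polygons",
    "polygon_cell_weights",
    "spherical_area_km2",
]

# Planar area (deg^2) below which an intersection is treated as
# boundary-only contact; ~1e-2 m^2 at the equator.
_EPS_AREA_DEG2 = 1e-12

# Densification step (deg) applied before the equal-area transform.
_SEGMENTIZE_DEG = 0.05

_WORLD = box(-180.0, -90.0, 180.0, 90.0)


class GeometryError(ValueError):
    """Invalid, empty, or out-of-domain range geometry."""


@dataclass(frozen=True)
class RangePolygonSet:
    """One species' expert range as normalized lon-lat polygons.

    Construct via :func:`RangePolygonSet.from_geometry`, which repairs
    invalid rings, normalizes longitudes into [-180, 180] and splits
    antimeridian-crossing parts.
    """

    species_id: str
    polygons: tuple[Polygon, ...]
    subpopulation_label: str | None = None

    @staticmethod
    def from_geometry(
        species_id: str,
        geometry: BaseGeometry,
        subpopulation_label: str | None = None,
    ) -> "RangePolygonSet":
        norm = normalize_geometry(geometry)
        parts = tuple(norm.geoms) if isinstance(norm, MultiPolygon) else (norm,)
        return RangePolygonSet(species_id, parts, subpopulation_label)

    def union(self) -> BaseGeometry:
        return shapely.union_all(list(self.polygons))


def _repair(geom: BaseGeometry) -> BaseGeometry:
    if geom.is_empty:
        raise GeometryError("empty geometry")
    if not geom.is_valid:
        geom = geom.buffer(0)
    geom = shapely.union_all([g for g in _polygon_parts(geom)])
    if geom.is_empty or geom.area <= 0:
        raise GeometryError("geometry has no repairable positive-area part")
    if not geom.is_valid:
        raise GeometryError("geometry irreparable by zero-width buffering")
    return geom


def _polygon_parts(geom: BaseGeometry) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    if geom.geom_type == "GeometryCollection":
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_polygon_parts(g))
        return out
    raise GeometryError(f"expected polygonal geometry, got {geom.geom_type}")


def normalize_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Repair, wrap longitudes into [-180, 180] and clip to the world box."""
    geom = _repair(geom)
    _, lat0, _, lat1 = geom.bounds
    if lat0 < -90.0 - 1e-9 or lat1 > 90.0 + 1e-9:
        raise GeometryError(
            f"latitudes [{lat0}, {lat1}] extend outside [-90, 90]"
        )
    lon0, _, lon1, _ = geom.bounds
    k_min = math.floor((lon0 + 180.0) / 360.0)
    k_max = math.ceil((lon1 + 180.0) / 360.0 - 1.0)
    parts = []
    for k in range(k_min, k_max + 1):
        shifted = translate(geom, xoff=-360.0 * k) if k else geom
        clipped = shifted.intersection(_WORLD)
        if clipped.area > 0:
            parts.append(clipped)
    if not parts:
        raise GeometryError("geometry lies outside the lon-lat domain")
    merged = shapely.union_all(parts)
    return shapely.union_all(_polygon_parts(merged))


def _candidate_cells(
    grid: GridSpec, bounds: tuple[float, float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Row and column index arrays for cells whose interior may meet `bounds`."""
    res = grid.resolution_deg
    lon0, lat0, lon1, lat1 = bounds
    c0 = max(0, int(math.floor((lon0 + 180.0) / res)))
    c1 = min(grid.n_cols - 1, int(math.ceil((lon1 + 180.0) / res)) - 1)
    r0 = max(0, int(math.floor((90.0 - lat1) / res)))
    r1 = min(grid.n_rows - 1, int(math.ceil((90.0 - lat0) / res)) - 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows, cols = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    return rows.ravel(), cols.ravel()


def _cell_boxes(grid: GridSpec, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    res = grid.resolution_deg
    lon_w = -180.0 + cols * res
    lat_n = 90.0 - rows * res
    return shapely.box(lon_w, lat_n - res, lon_w + res, lat_n)


def _intersections(
    geom: BaseGeometry, grid: GridSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, cols, intersection geometries) for positive-area overlaps."""
    rows, cols = _candidate_cells(grid, geom.bounds)
    if rows.size == 0:
        return rows, cols, np.empty(0, dtype=object)
    boxes = _cell_boxes(grid, rows, cols)
    shapely.prepare(geom)
    hit = shapely.intersects(geom, boxes)
    rows, cols, boxes = rows[hit], cols[hit], boxes[hit]
    inter = shapely.intersection(geom, boxes)
    pos = shapely.area(inter) > _EPS_AREA_DEG2
    return rows[pos], cols[pos], inter[pos]


def rasterize_polygons(ranges: RangePolygonSet, grid: GridSpec) -> PresenceRaster:
    """Mark a cell present iff the range polygon overlaps any portion of it.

    "Any portion" means strictly positive intersection area; a polygon
    covering 1% of a cell still marks it present, while edge or vertex
    contact alone does not.
    """
    occupied: set[tuple[int, int]] = set()
    for poly in ranges.polygons:
        rows, cols, _ = _intersections(poly, grid)
        occupied.update(zip(rows.tolist(), cols.tolist()))
    return PresenceRaster(ranges.species_id, grid, frozenset(occupied))


def spherical_area_km2(
    geom: BaseGeometry,
    earth_radius_km: float = 6371.0,
    segmentize_deg: float = _SEGMENTIZE_DEG,
) -> float:
    """Spherical area of a lon-lat geometry via the equal-area transform.

    Exact for regions bounded by meridian and parallel segments (grid-cell
    rectangles and their bisections); oblique edges are densified to
    `segmentize_deg` so chord error is negligible at grid scale.
    """
    if geom.is_empty:
        return 0.0
    dense = shapely.segmentize(geom, segmentize_deg)

    def to_equal_area(coords: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        out[:, 0] = np.radians(coords[:, 0])
        out[:, 1] = np.sin(np.radians(coords[:, 1]))
        return out

    return float(shapely.transform(dense, to_equal_area).area) * earth_radius_km**2


def polygon_cell_weights(
    ranges: RangePolygonSet, grid: GridSpec
) -> CoverageWeightRaster:
    """Fraction of each cell's spherical area covered by the range polygon."""
    areas = grid.row_areas_km2()
    weights: dict[tuple[int, int], float] = {}
    merged = ranges.union()
    for poly in _polygon_parts(merged):
        rows, cols, inter = _intersections(poly, grid)
        for r, c, g in zip(rows.tolist(), cols.tolist(), inter):
            w = spherical_area_km2(g, grid.earth_radius_km) / areas[r]
            w = min(w, 1.0)
            if w > 0.0:
                weights[(r, c)] = weights.get((r, c), 0.0) + w
    weights = {cell: min(w, 1.0) for cell, w in weights.items() if w > 1e-15}
    return CoverageWeightRaster(ranges.species_id, grid, weights)
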