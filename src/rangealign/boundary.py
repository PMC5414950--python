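"""Detecting artificial range edges at georegion boundary meridians.

Model-generated distributions constrained to statistical ocean regions
(FAO-style areas with straight-line borders) can end abruptly exactly at a
boundary meridian rather than at an ecological limit. The scan crops each
range to a latitudinal band, finds the eastern (or western) edge of the
cropped range within a user-supplied longitude domain, and flags species
whose edge lies exactly on a boundary meridian. The extrapolation-rate
metric (range area per occurrence cell) quantifies how far a map is
extrapolated from the data that generated it.

Longitude domains are directed intervals traversed eastward from their
western limit and may wrap across the antimeridian (e.g. 20E -> 140W for
the Indo-Pacific); the domain's own seam is excluded, which removes the
wrap ambiguity of a circular coordinate. Edges are compared as cell-edge
longitudes, never cell centers, and "coincides" means exact grid-line
equality, not a tolerance window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .grid import GridError, GridSpec
from .rasters import PresenceRaster

__all__ = [
    "LatBand",
    "BoundaryMeridian",
    "EdgeHit",
    "crop_band",
    "range_edge",
    "boundary_coincidence",
    "extrapolation_rate",
]

_TOL = 1e-9


def _norm_lon(lon: float, side: str = "east") -> float:
    """Normalize into [-180, 180]; the antimeridian reports as 180 for an
    eastern edge and -180 for a western edge."""
    out = ((lon + 180.0) % 360.0) - 180.0
    if abs(out + 180.0) < _TOL and side == "east":
        return 180.0
    return out


@dataclass(frozen=True)
class LatBand:
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError(f"invalid band [{self.lat_min}, {self.lat_max}]")


@dataclass(frozen=True)
class BoundaryMeridian:
    longitude: float
    label: str = ""

    def on_grid(self, grid: GridSpec) -> bool:
        k = (self.longitude + 180.0) / grid.resolution_deg
        return abs(k - round(k)) < _TOL


@dataclass(frozen=True)
class EdgeHit:
    species_id: str
    side: str  # "east" or "west"
    meridian: BoundaryMeridian
    cells_at_edge: int

    def __post_init__(self) -> None:
        if self.cells_at_edge < 1:
            raise ValueError("an edge hit needs at least one cell at the edge")


def crop_band(pres: PresenceRaster, band: LatBand) -> PresenceRaster:
    """Keep cells whose full latitude span lies within the band."""
    grid = pres.grid
    res = grid.resolution_deg
    if band.lat_max - band.lat_min < res - _TOL:
        raise ValueError(
            f"band [{band.lat_min}, {band.lat_max}] narrower than one "
            f"{res} deg cell row"
        )
    kept = set()
    for (r, c) in pres.occupied:
        lat_top = 90.0 - r * res
        lat_bot = lat_top - res
        if lat_bot >= band.lat_min - _TOL and lat_top <= band.lat_max + _TOL:
            kept.add((r, c))
    return PresenceRaster(pres.species_id, grid, frozenset(kept))


def _unwrap(lon: float, domain_west: float) -> float:
    """Eastward offset of `lon` from the domain's western limit, in [0, 360)."""
    return (lon - domain_west) % 360.0


def range_edge(
    pres_band: PresenceRaster,
    side: str,
    domain: tuple[float, float],
) -> float:
    """Outer-edge longitude of the extreme occupied cell within the domain.

    `domain` is (west, east) traversed eastward and must not be degenerate;
    only cells whose full longitude span lies inside the domain are
    considered. For side="east" the result is the maximum eastern cell-edge
    longitude, for "west" the minimum western cell-edge longitude, returned
    in (-180, 180].
    """
    if side not in ("east", "west"):
        raise ValueError(f"side must be 'east' or 'west', got {side!r}")
    west, east = domain
    length = (east - west) % 360.0
    if length == 0.0:
        raise ValueError("degenerate longitude domain")
    res = pres_band.grid.resolution_deg
    offsets = []
    for (_, c) in pres_band.occupied:
        w_edge = -180.0 + c * res
        u = _unwrap(w_edge, west)
        if u + res <= length + _TOL:
            offsets.append(u)
    if not offsets:
        raise ValueError(
            f"no occupied cells within domain [{west}, {east}] for "
            f"{pres_band.species_id}"
        )
    if side == "east":
        u_edge = max(offsets) + res
    else:
        u_edge = min(offsets)
    return _norm_lon(west + u_edge, side)


def boundary_coincidence(
    rasters: Iterable[PresenceRaster],
    band: LatBand,
    meridians: Sequence[BoundaryMeridian],
    side: str = "east",
    domain: tuple[float, float] = (20.0, -140.0),
) -> list[EdgeHit]:
    """Flag species whose cropped range edge coincides exactly with a
    boundary meridian.

    Species ending short of, or spanning across, a meridian are not
    flagged; only exact cell-edge equality counts.
    """
    rasters = list(rasters)
    hits: list[EdgeHit] = []

    def same_meridian(a: float, b: float) -> bool:
        return abs(a - b) < _TOL or abs(abs(a - b) - 360.0) < _TOL

    for m in meridians:
        if rasters and not m.on_grid(rasters[0].grid):
            raise GridError(
                f"meridian {m.longitude} not on a "
                f"{rasters[0].grid.resolution_deg} deg grid line"
            )
        for ras in rasters:
            cropped = crop_band(ras, band)
            if not cropped.occupied:
                continue
            try:
                edge = range_edge(cropped, side, domain)
            except ValueError:  # nothing inside the longitude domain
                continue
            if not same_meridian(edge, m.longitude):
                continue
            res = cropped.grid.resolution_deg
            at_edge = 0
            for (_, c) in cropped.occupied:
                w_edge = -180.0 + c * res
                outer = w_edge + res if side == "east" else w_edge
                if same_meridian(outer, m.longitude):
                    at_edge += 1
            hits.append(EdgeHit(ras.species_id, side, m, at_edge))
    return hits


def extrapolation_rate(area_km2: float, occurcells: int) -> float:
    """km^2 of predicted range per occurrence cell; undefined for zero cells.

    Maps built from few occurrence cells (fewer than about 10) warrant
    caution: large rates mean aggressive extrapolation from little data.
    """
    if occurcells < 1:
        raise ValueError(
            "extrapolation rate undefined: occurcells must be at least 1"
        )
    if area_km2 < 0:
        raise ValueError("negative area")
    return area_km2 / occurcells
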