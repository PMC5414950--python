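"""Global equal-angle (plate carrée) grid: indexing and geodesic cell areas.

The grid covers the full lon-lat domain [-180, 180] x [-90, 90] at a
resolution that divides 180 evenly (default 0.5 degrees, the native
resolution of global marine distribution products). Row 0 abuts 90N,
column 0 abuts 180W. Cell (r, c) spans

    lon in [-180 + c*res, -180 + (c+1)*res)          (west-closed)
    lat in (90 - (r+1)*res,  90 - r*res]             (top-closed)

so every point maps to exactly one cell; the two exceptions forced by a
finite domain are lon = 180 (identified with -180, column 0) and
lat = -90 (clamped into the southernmost row).

Cell areas are geodesic on a sphere of authalic radius 6371 km, using the
spherical-zone formula R^2 * dlam * (sin(phi_top) - sin(phi_bot)); areas
are identical for all cells in a row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["GridError", "GridSpec", "make_grid", "cell_area_km2", "row_areas_km2"]


class GridError(ValueError):
    """Invalid grid construction or cell indexing."""


@dataclass(frozen=True)
class GridSpec:
    """An equal-angle global grid.

    Parameters
    ----------
    resolution_deg
        Cell size in degrees; must divide 180 evenly.
    earth_radius_km
        Radius of the spherical Earth used for all areas (authalic radius).
    """

    resolution_deg: float = 0.5
    earth_radius_km: float = 6371.0

    def __post_init__(self) -> None:
        res = self.resolution_deg
        if not (isinstance(res, (int, float)) and res > 0):
            raise GridError(f"grid resolution must be positive, got {res!r}")
        n = 180.0 / res
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"grid resolution {res} deg does not divide 180 evenly"
            )
        if self.earth_radius_km <= 0:
            raise GridError("earth radius must be positive")

    @property
    def n_rows(self) -> int:
        return round(180.0 / self.resolution_deg)

    @property
    def n_cols(self) -> int:
        return round(360.0 / self.resolution_deg)

    # ---- indexing ---------------------------------------------------------

    def validate_cell(self, row: int, col: int) -> None:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise GridError(
                f"cell ({row}, {col}) outside grid "
                f"{self.n_rows} rows x {self.n_cols} cols"
            )

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_west, lat_south, lon_east, lat_north) of a cell rectangle."""
        self.validate_cell(row, col)
        res = self.resolution_deg
        lon_w = -180.0 + col * res
        lat_n = 90.0 - row * res
        return lon_w, lat_n - res, lon_w + res, lat_n

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon_w, lat_s, lon_e, lat_n = self.cell_bounds(row, col)
        return (lon_w + lon_e) / 2.0, (lat_s + lat_n) / 2.0

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a lon-lat point to its unique cell per the half-open convention."""
        if not (-90.0 <= lat <= 90.0):
            raise GridError(f"latitude {lat} outside [-90, 90]")
        if not math.isfinite(lon):
            raise GridError(f"non-finite longitude {lon}")
        res = self.resolution_deg
        lon = ((lon + 180.0) % 360.0) - 180.0  # wraps 180 -> -180
        col = int(math.floor((lon + 180.0) / res))
        col = min(max(col, 0), self.n_cols - 1)
        row = int(math.floor((90.0 - lat) / res))
        if row == self.n_rows:  # lat == -90: clamp the pole into the last row
            row -= 1
        return row, col

    # ---- areas ------------------------------------------------------------

    def cell_area_km2(self, row: int) -> float:
        """Spherical-zone area of any cell in `row`, in km^2."""
        if not (0 <= row < self.n_rows):
            raise GridError(f"row {row} outside [0, {self.n_rows})")
        return float(row_areas_km2(self)[row])

    def row_areas_km2(self) -> np.ndarray:
        """Per-row cell areas (km^2), length n_rows; read-only view."""
        return row_areas_km2(self)


@lru_cache(maxsize=32)
def row_areas_km2(grid: GridSpec) -> np.ndarray:
    res = grid.resolution_deg
    lat_top = 90.0 - np.arange(grid.n_rows) * res
    lat_bot = lat_top - res
    dlam = math.radians(res)
    areas = (
        grid.earth_radius_km**2
        * dlam
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )
    areas.setflags(write=False)
    return areas


def make_grid(resolution_deg: float = 0.5, earth_radius_km: float = 6371.0) -> GridSpec:
    """Build a validated global grid (rejects resolutions not dividing 180)."""
    return GridSpec(resolution_deg=resolution_deg, earth_radius_km=earth_radius_km)


def cell_area_km2(grid: GridSpec, row: int) -> float:
    return grid.cell_area_km2(row)
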