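"""Sparse per-species rasters on the global grid.

PresenceRaster is the common currency of the whole pipeline: a set of
occupied cells for one species. ProbabilityRaster holds a relative
probability of occurrence in (0, 1] per cell (absent cells mean zero),
as produced by habitat-suitability models; thresholding it yields a
presence map. CoverageWeightRaster carries the fraction of each cell
covered by a source polygon, used where fractional occupancy matters
(protected-area accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .grid import GridError, GridSpec

__all__ = [
    "PresenceRaster",
    "ProbabilityRaster",
    "CoverageWeightRaster",
    "RichnessResult",
    "threshold_presence",
    "range_area_km2",
    "species_richness",
]

Cell = tuple[int, int]


def _check_cells(grid: GridSpec, cells: Iterable[Cell]) -> None:
    n_r, n_c = grid.n_rows, grid.n_cols
    for r, c in cells:
        if not (0 <= r < n_r and 0 <= c < n_c):
            raise GridError(f"cell ({r}, {c}) outside {n_r}x{n_c} grid")


@dataclass(frozen=True)
class PresenceRaster:
    """Boolean occupancy of grid cells for one species."""

    species_id: str
    grid: GridSpec
    occupied: frozenset[Cell]

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupied", frozenset(self.occupied))
        _check_cells(self.grid, self.occupied)

    def __len__(self) -> int:
        return len(self.occupied)

    def area_km2(self) -> float:
        return range_area_km2(self)


@dataclass(frozen=True)
class ProbabilityRaster:
    """Relative probability of occurrence per cell; absent cells mean 0."""

    species_id: str
    grid: GridSpec
    values: Mapping[Cell, float]

    def __post_init__(self) -> None:
        vals = dict(self.values)
        _check_cells(self.grid, vals)
        for cell, p in vals.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(
                    f"probability {p} at cell {cell} outside (0, 1]; "
                    "zero-probability cells must simply be absent"
                )
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CoverageWeightRaster:
    """Fraction of each cell's area covered by the source polygon, in (0, 1]."""

    species_id: str
    grid: GridSpec
    weights: Mapping[Cell, float]

    def __post_init__(self) -> None:
        w = dict(self.weights)
        _check_cells(self.grid, w)
        for cell, v in w.items():
            if not (0.0 < v <= 1.0 + 1e-12):
                raise ValueError(f"coverage weight {v} at cell {cell} outside (0, 1]")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def to_presence(self) -> PresenceRaster:
        return PresenceRaster(self.species_id, self.grid, frozenset(self.weights))


def threshold_presence(prob: ProbabilityRaster, t: float) -> PresenceRaster:
    """Presence from a probability raster.

    t = 0 keeps every cell with strictly positive probability (the
    "non-zero probability" extent-of-occurrence reading); t > 0 keeps
    cells with probability >= t (the "t or greater" reading).
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold {t} outside [0, 1]")
    if t == 0.0:
        cells = frozenset(prob.values)
    else:
        cells = frozenset(c for c, p in prob.values.items() if p >= t)
    return PresenceRaster(prob.species_id, prob.grid, cells)


def range_area_km2(pres: PresenceRaster) -> float:
    """Total geodesic area of the occupied cells, km^2.

    Uses exact (order-independent) float summation so equal cell sets give
    bit-equal areas.
    """
    import math

    areas = pres.grid.row_areas_km2()
    return math.fsum(areas[r] for r, _ in pres.occupied)


@dataclass(frozen=True)
class RichnessResult:
    """Per-cell species counts with row/column marginals."""

    grid: GridSpec
    counts: Mapping[Cell, int]
    lat_marginal: np.ndarray  # length n_rows
    lon_marginal: np.ndarray  # length n_cols
    marginal: str  # "sum" or "max"


def species_richness(
    rasters: Iterable[PresenceRaster], marginal: str = "sum"
) -> RichnessResult:
    """Count species per cell and reduce to latitudinal/longitudinal marginals.

    `marginal="sum"` sums counts across each row/column; `"max"` takes the
    row/column maximum (a "relative species count" profile).
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("species_richness needs at least one raster")
    grid = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != grid:
            raise GridError("all rasters must share one grid")
    if marginal not in ("sum", "max"):
        raise ValueError(f"marginal must be 'sum' or 'max', got {marginal!r}")

    counts: dict[Cell, int] = {}
    for ras in rasters:
        for cell in ras.occupied:
            counts[cell] = counts.get(cell, 0) + 1

    lat = np.zeros(grid.n_rows, dtype=np.int64)
    lon = np.zeros(grid.n_cols, dtype=np.int64)
    for (r, c), n in counts.items():
        if marginal == "sum":
            lat[r] += n
            lon[c] += n
        else:
            lat[r] = max(lat[r], n)
            lon[c] = max(lon[c], n)
    return RichnessResult(grid, counts, lat, lon, marginal)
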