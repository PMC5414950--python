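"""Depth-based range clipping and its effect on alignment.

Expert extent-of-occurrence maps for shallow-water taxa (reef corals in
particular) routinely extend over abyssal water where the species cannot
occur. Clipping a presence raster to cells shallower than a species'
maximum depth removes that commission error. A cell is kept when its
minimum depth is strictly less than the limit — any shallow sliver keeps
the cell, mirroring the generosity of the any-overlap presence rule.
Depths are meters, positive downward; land and no-data cells are simply
absent from the bathymetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    AlignmentResult,
    QuadrantLabel,
    QuadrantThresholds,
    classify_quadrant,
)
from .grid import GridError, GridSpec
from .rasters import PresenceRaster, range_area_km2

__all__ = [
    "BathymetryRaster",
    "DepthMask",
    "build_depth_mask",
    "clip_presence",
    "eliminated_fraction",
    "reclassification_table",
    "aggregate_bathymetry_min",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class BathymetryRaster:
    """Minimum water depth per marine cell (m, positive downward).

    Cells not in `depth_m` are land or no-data. Rasters supplied with a
    negative-down convention should be negated on read (io helpers do this
    with a logged notice).
    """

    grid: GridSpec
    depth_m: Mapping[Cell, float]

    def __post_init__(self) -> None:
        d = dict(self.depth_m)
        for cell, v in d.items():
            self.grid.validate_cell(*cell)
            if v < 0:
                raise ValueError(
                    f"negative depth {v} at {cell}; depths are positive downward"
                )
        object.__setattr__(self, "depth_m", d)


@dataclass(frozen=True)
class DepthMask:
    grid: GridSpec
    allowed: frozenset[Cell]
    max_depth_m: float


def build_depth_mask(bathy: BathymetryRaster, max_depth_m: float) -> DepthMask:
    """Cells whose minimum depth is strictly shallower than the limit."""
    if max_depth_m <= 0:
        raise ValueError(f"max depth must be positive, got {max_depth_m}")
    allowed = frozenset(
        cell for cell, d in bathy.depth_m.items() if d < max_depth_m
    )
    if not allowed:
        warnings.warn(
            f"depth mask at {max_depth_m} m is empty "
            f"({len(bathy.depth_m)} marine cells, none shallower)",
            stacklevel=2,
        )
    return DepthMask(bathy.grid, allowed, max_depth_m)


def aggregate_bathymetry_min(
    fine_depth: np.ndarray,
    fine_resolution_deg: float,
    grid: GridSpec,
    origin: Cell = (0, 0),
) -> BathymetryRaster:
    """Aggregate a finer bathymetry array to the grid by block minimum.

    `fine_depth` is a 2D array (NaN = land/no-data) whose top-left corner
    coincides with the top-left corner of coarse cell `origin`. All-NaN
    blocks are omitted (no marine data).
    """
    factor = grid.resolution_deg / fine_resolution_deg
    if abs(factor - round(factor)) > 1e-9:
        raise GridError(
            f"fine resolution {fine_resolution_deg} does not nest in "
            f"{grid.resolution_deg}"
        )
    f = round(factor)
    n_r, n_c = fine_depth.shape
    if n_r % f or n_c % f:
        raise GridError("fine array shape must be a multiple of the nesting factor")
    blocks = fine_depth.reshape(n_r // f, f, n_c // f, f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        mins = np.nanmin(blocks, axis=(1, 3))
    depth: dict[Cell, float] = {}
    r0, c0 = origin
    for i in range(mins.shape[0]):
        for j in range(mins.shape[1]):
            v = mins[i, j]
            if not np.isnan(v):
                depth[(r0 + i, c0 + j)] = float(v)
    return BathymetryRaster(grid, depth)


def clip_presence(pres: PresenceRaster, mask: DepthMask) -> PresenceRaster:
    if pres.grid != mask.grid:
        raise GridError("presence and depth mask on different grids")
    return PresenceRaster(pres.species_id, pres.grid, pres.occupied & mask.allowed)


def eliminated_fraction(before: PresenceRaster, after: PresenceRaster) -> float:
    """Percent of the pre-clip area removed by clipping."""
    if not before.occupied:
        raise ValueError("eliminated fraction undefined for an empty range")
    if not after.occupied <= before.occupied:
        raise ValueError("clipped raster is not a subset of the original")
    a0, a1 = range_area_km2(before), range_area_km2(after)
    return 100.0 * (a0 - a1) / a0


def reclassification_table(
    results_before: Sequence[AlignmentResult],
    results_after: Sequence[AlignmentResult],
    th: QuadrantThresholds,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quadrant transition matrix and before/after membership percentages.

    Thresholds are held fixed (at the pre-clip cohort means) so the after
    column reports movement against the same quadrant boundaries. Returns
    (transitions, membership): `transitions` is a 4x4 count matrix indexed
    by from-quadrant with to-quadrant columns; `membership` has pct_before
    and pct_after per quadrant.
    """
    before = {r.canonical_id: r for r in results_before}
    after = {r.canonical_id: r for r in results_after}
    if before.keys() != after.keys():
        missing = before.keys() ^ after.keys()
        raise ValueError(f"species sets differ between runs: {sorted(missing)[:5]}")
    labels = [q.value for q in QuadrantLabel]
    trans = pd.DataFrame(0, index=labels, columns=labels)
    for cid, rb in before.items():
        qb = classify_quadrant(rb, th).value
        qa = classify_quadrant(after[cid], th).value
        trans.loc[qb, qa] += 1
    n = len(before)
    membership = pd.DataFrame(
        {
            "quadrant": labels,
            "pct_before": [100.0 * trans.loc[q].sum() / n for q in labels],
            "pct_after": [100.0 * trans[q].sum() / n for q in labels],
        }
    )
    return trans, membership
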