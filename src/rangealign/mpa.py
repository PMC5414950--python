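"""Marine-protected-area coverage gap analysis.

A fine-resolution protected-area mask (default 0.01 deg) is aggregated to
the analysis grid as the fraction of *marine* fine cells in each block
that are protected; cells with no marine portion carry no value. Each
species' protected range fraction is then the protection-weighted share of
its range,

    protected_pct = 100 * sum(w * f * A) / sum(w * A)

over occupied cells, where f is the cell's protected fraction, A its
geodesic area, and w either 1 (binary presence) or the polygon coverage
weight (fractional occupancy of expert ranges). Species are binned as
gap (exactly zero protection), <2%, 2-5%, 5-10% and >=10% of range
protected; cohort "<5%" figures are gap + <2% + 2-5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridError, GridSpec
from .rasters import CoverageWeightRaster, PresenceRaster

__all__ = [
    "ProtectionRaster",
    "ProtectionBin",
    "ProtectionSummary",
    "aggregate_protection",
    "protected_fraction",
    "protection_cohort_summary",
]

Cell = tuple[int, int]


class ProtectionBin(str, Enum):
    GAP = "gap"        # exactly 0
    LT2 = "lt2"        # (0, 2)
    LT5 = "lt5"        # [2, 5)
    B5TO10 = "b5to10"  # [5, 10)
    GE10 = "ge10"      # [10, 100]


_EDGE_TOL = 1e-9  # keeps exact boundary percentages out of the lower bin


def _bin_for(protected_pct: float, is_gap: bool) -> ProtectionBin:
    if is_gap:
        return ProtectionBin.GAP
    if protected_pct < 2.0 - _EDGE_TOL:
        return ProtectionBin.LT2
    if protected_pct < 5.0 - _EDGE_TOL:
        return ProtectionBin.LT5
    if protected_pct < 10.0 - _EDGE_TOL:
        return ProtectionBin.B5TO10
    return ProtectionBin.GE10


@dataclass(frozen=True)
class ProtectionRaster:
    """Fraction of each cell's marine area covered by protected area."""

    grid: GridSpec
    fraction: Mapping[Cell, float]

    def __post_init__(self) -> None:
        f = dict(self.fraction)
        for cell, v in f.items():
            self.grid.validate_cell(*cell)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"protection fraction {v} at {cell} outside [0, 1]")
        object.__setattr__(self, "fraction", f)


@dataclass(frozen=True)
class ProtectionSummary:
    species_id: str
    range_area_km2: float
    protected_area_km2: float
    protected_pct: float
    bin: ProtectionBin


def aggregate_protection(
    fine_marine: np.ndarray,
    fine_protected: np.ndarray,
    fine_resolution_deg: float,
    grid: GridSpec,
    origin: Cell = (0, 0),
) -> ProtectionRaster:
    """Aggregate fine boolean marine/protected masks to per-cell fractions.

    Both arrays are 2D booleans at `fine_resolution_deg`, top-left corner
    aligned with the top-left corner of coarse cell `origin`; the fine
    resolution must nest evenly in the grid resolution. The coarse value is
    (protected & marine fine cells) / (marine fine cells) per block; blocks
    without marine cells are absent.
    """
    factor = grid.resolution_deg / fine_resolution_deg
    if abs(factor - round(factor)) > 1e-9:
        raise GridError(
            f"fine resolution {fine_resolution_deg} does not nest evenly in "
            f"{grid.resolution_deg}"
        )
    f = round(factor)
    marine = np.asarray(fine_marine, dtype=bool)
    protected = np.asarray(fine_protected, dtype=bool)
    if marine.shape != protected.shape:
        raise ValueError("marine and protected masks must share a shape")
    n_r, n_c = marine.shape
    if n_r % f or n_c % f:
        raise GridError("fine mask shape must be a multiple of the nesting factor")

    def block_sum(a: np.ndarray) -> np.ndarray:
        return a.reshape(n_r // f, f, n_c // f, f).sum(axis=(1, 3))

    marine_counts = block_sum(marine)
    prot_counts = block_sum(protected & marine)
    r0, c0 = origin
    fraction: dict[Cell, float] = {}
    for i, j in zip(*np.nonzero(marine_counts)):
        grid.validate_cell(r0 + int(i), c0 + int(j))
        fraction[(r0 + int(i), c0 + int(j))] = float(
            prot_counts[i, j] / marine_counts[i, j]
        )
    return ProtectionRaster(grid, fraction)


def protected_fraction(
    presence_or_weights: PresenceRaster | CoverageWeightRaster,
    prot: ProtectionRaster,
    area_weighted: bool = True,
) -> ProtectionSummary:
    """Protected share of one species' range.

    Accepts binary presence or polygon coverage weights; `area_weighted=False`
    switches from geodesic-area weighting to plain cell counting. A species
    is a gap species iff no occupied cell has positive protection.
    """
    if isinstance(presence_or_weights, CoverageWeightRaster):
        cells = presence_or_weights.weights
        sid = presence_or_weights.species_id
        grid = presence_or_weights.grid
    else:
        cells = {c: 1.0 for c in presence_or_weights.occupied}
        sid = presence_or_weights.species_id
        grid = presence_or_weights.grid
    if grid != prot.grid:
        raise GridError("range and protection rasters on different grids")
    if not cells:
        raise ValueError(f"empty range for {sid}")

    areas = grid.row_areas_km2()
    tot = 0.0
    prot_tot = 0.0
    any_protected = False
    for (r, c), w in cells.items():
        a = float(areas[r]) if area_weighted else 1.0
        f = prot.fraction.get((r, c), 0.0)
        tot += w * a
        prot_tot += w * f * a
        if f > 0.0:
            any_protected = True
    pct = 100.0 * prot_tot / tot
    return ProtectionSummary(
        species_id=sid,
        range_area_km2=tot if area_weighted else float("nan"),
        protected_area_km2=prot_tot if area_weighted else float("nan"),
        protected_pct=pct,
        bin=_bin_for(pct, not any_protected),
    )


def protection_cohort_summary(
    summaries_by_scenario: Mapping[str, Sequence[ProtectionSummary]],
) -> pd.DataFrame:
    """Percent of species per protection bin per scenario (rows sum to 100).

    Scenarios typically differ by input dataset and presence threshold
    (e.g. model maps at a 50% threshold, at 0%, and expert polygon weights).
    A `lt5_cumulative` convenience column reports gap + <2% + 2-5%.
    """
    rows = []
    for scenario, summaries in summaries_by_scenario.items():
        if not summaries:
            raise ValueError(f"scenario {scenario!r} has no species")
        n = len(summaries)
        counts = {b: 0 for b in ProtectionBin}
        for s in summaries:
            counts[s.bin] += 1
        row = {"scenario": scenario, "n": n}
        for b in ProtectionBin:
            row[b.value] = 100.0 * counts[b] / n
        row["lt5_cumulative"] = (
            row["gap"] + row["lt2"] + row["lt5"]
        )
        rows.append(row)
    return pd.DataFrame(rows)
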