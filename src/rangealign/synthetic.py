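"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of paired marine range
data: expert extent-of-occurrence polygons versus model probability-of-
occurrence rasters with controllable overlap fraction and size ratio,
a shelf-like linear bathymetry, meridian-truncated equatorial ranges, and
patchy protected-area coverage with an exactly known protected fraction.

Ranges are built as grid-aligned rectangular blocks spanning a fixed set
of rows, so the configured overlap fraction and size ratio are achieved
combinatorially (exactly, up to one column of rounding) rather than by
rejection sampling: because both members of a pair span the same rows,
per-row geodesic areas cancel and area ratios reduce to column-count
ratios. Default cohort parameters (size ratio 0.548, overlap 0.35 of the
larger range, i.e. ~0.64 of the smaller) reflect the alignment level
observed between global expert and model range products.

Everything is deterministic: one seed, fed through per-operation
``numpy.random.default_rng`` seed sequences, fixes all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from shapely.geometry import box

from .grid import GridSpec
from .habitat import BathymetryRaster
from .pairing import Dataset, SpeciesRecord, SynonymTable
from .polygons import RangePolygonSet
from .rasters import PresenceRaster, ProbabilityRaster

__all__ = [
    "SimConfig",
    "GenPair",
    "DrownedPair",
    "TruncatedCohort",
    "ProtectionScene",
    "gen_range_pair",
    "gen_cohort",
    "gen_bathymetry",
    "gen_drowned_pairs",
    "gen_truncated_ranges",
    "gen_protection",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; identical config + seed give identical outputs.

    overlap_fraction is the overlap as a fraction of the *larger* range and
    must not exceed size_ratio (overlap cannot exceed the smaller range).
    cohort_spread is the half-width of the per-species uniform jitter
    applied around the configured overlap/size targets.
    """

    seed: int = 0
    n_species: int = 150
    grid: GridSpec = field(default_factory=GridSpec)
    overlap_fraction: float = 0.35
    size_ratio: float = 0.548
    cohort_spread: float = 0.18
    n_cells_large: int = 400
    rows_per_range: int = 10
    polygon_larger_prob: float = 0.5
    redlist_id_fraction: float = 0.6
    synonym_fraction: float = 0.2
    # shelf bathymetry: land west of coast_lon, depth increasing eastward
    coast_lon: float = -20.0
    shelf_slope_m_per_deg: float = 20.0
    shelf_extent_deg: float = 60.0
    drowned_fraction: float = 0.478
    # georegion truncation
    truncation_meridian: float = -175.0
    truncated_fraction: float = 0.3
    # protected areas
    protection_fraction: float = 0.02
    fine_resolution_deg: float = 0.1
    # heavy-tailed occurrence-cell law (lognormal)
    occurcell_log_mean: float = 3.0
    occurcell_log_sigma: float = 1.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction outside [0, 1]")
        if not (0.0 < self.size_ratio <= 1.0):
            raise ValueError("size_ratio outside (0, 1]")
        if self.overlap_fraction > self.size_ratio + 1e-12:
            raise ValueError(
                "infeasible configuration: overlap_fraction exceeds size_ratio "
                "(the overlap cannot exceed the smaller range)"
            )
        if not (0.0 <= self.protection_fraction <= 1.0):
            raise ValueError("protection_fraction outside [0, 1]")
        if not (0.0 <= self.truncated_fraction <= 1.0):
            raise ValueError("truncated_fraction outside [0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), *key])


def _rect_cells(rows: range, cols: Iterable[int], n_cols: int) -> frozenset[Cell]:
    return frozenset((r, c % n_cols) for r in rows for c in cols)


@dataclass(frozen=True)
class GenPair:
    """One synthetic paired-map species with its planted ground truth."""

    polygons: RangePolygonSet
    probability: ProbabilityRaster
    record_a: SpeciesRecord  # expert polygons dataset
    record_b: SpeciesRecord  # model raster dataset
    overlap_fraction_true: float  # achieved overlap / larger, after rounding
    size_ratio_true: float        # achieved smaller / larger
    polygon_is_larger: bool
    synonym_variant: tuple[str, str] | None  # (variant, canonical) or None


def gen_range_pair(cfg: SimConfig, species_index: int) -> GenPair:
    """Build one polygon/probability range pair.

    The thresholded (t = 0.5) model footprint overlaps the rasterized
    polygon by ~cfg.overlap_fraction of the larger range and has area ratio
    ~cfg.size_ratio, jittered per species; achieved values are reported in
    the ground truth. Probabilities decay linearly from the habitat
    centroid within the footprint (values >= 0.5) and drop below 0.5 in a
    two-cell fringe around it, so a zero threshold widens the range.
    """
    rng = _rng(cfg, 1, species_index)
    grid = cfg.grid
    res = grid.resolution_deg

    s = cfg.cohort_spread
    rho = float(np.clip(cfg.size_ratio + rng.uniform(-s, s), 0.05, 1.0))
    f = float(np.clip(cfg.overlap_fraction + rng.uniform(-s, s), 0.0, 1.0))
    f = min(f, rho)

    h = cfg.rows_per_range
    w = max(2, round(cfg.n_cells_large / h))
    w_small = max(1, round(rho * w))
    k = min(int(round(f * w)), w_small)

    row_center = grid.n_rows // 2 + int(rng.integers(-20, 21))
    top = row_center - h // 2
    rows = range(top, top + h)
    lon0 = float(rng.uniform(-150.0, 80.0))
    c0 = int(math.floor((lon0 + 180.0) / res))

    large_cols = range(c0, c0 + w)
    small_start = c0 + w - k
    small_cols = range(small_start, small_start + w_small)

    polygon_is_larger = bool(rng.random() < cfg.polygon_larger_prob)
    poly_cols = large_cols if polygon_is_larger else small_cols
    model_cols = small_cols if polygon_is_larger else large_cols

    lat_n = 90.0 - top * res
    lat_s = lat_n - h * res
    poly_geom = box(
        -180.0 + poly_cols.start * res,
        lat_s,
        -180.0 + poly_cols.stop * res,
        lat_n,
    )
    sid_a, sid_b = f"a{species_index:04d}", f"b{species_index:04d}"
    polygons = RangePolygonSet.from_geometry(sid_a, poly_geom)

    values: dict[Cell, float] = {}
    cc = (model_cols.start + model_cols.stop - 1) / 2.0
    max_d = max((model_cols.stop - model_cols.start - 1) / 2.0, 1.0)
    n_cols = grid.n_cols
    for r in rows:
        for c in model_cols:
            values[(r, c % n_cols)] = round(
                1.0 - 0.45 * min(abs(c - cc) / max_d, 1.0), 6
            )
    # sub-threshold fringe: first ring 0.25, second ring 0.1
    for ring, p in ((1, 0.25), (2, 0.1)):
        for r in range(top - ring, top + h + ring):
            for c in range(model_cols.start - ring, model_cols.stop + ring):
                cell = (r, c % n_cols)
                if 0 <= r < grid.n_rows and cell not in values:
                    values[cell] = p
    probability = ProbabilityRaster(sid_b, grid, values)

    canonical = f"Simulatus sim{species_index:04d}"
    variant = None
    binomial_b = canonical
    if rng.random() < cfg.synonym_fraction:
        binomial_b = canonical + "um"
        variant = (binomial_b, canonical)
    redlist = (
        str(100000 + species_index)
        if rng.random() < cfg.redlist_id_fraction
        else None
    )
    occurcells = max(
        1,
        int(round(math.exp(rng.normal(cfg.occurcell_log_mean, cfg.occurcell_log_sigma)))),
    )
    record_a = SpeciesRecord(
        dataset=Dataset.EXPERT_POLYGONS,
        species_id=sid_a,
        binomial=canonical,
        redlist_id=redlist,
        occurrence_records=occurcells * int(rng.integers(2, 8)),
        depth_max_m=200.0 if rng.random() < 0.3 else None,
    )
    record_b = SpeciesRecord(
        dataset=Dataset.MODEL_RASTER,
        species_id=sid_b,
        binomial=binomial_b,
        redlist_id=redlist,
        occurcells=occurcells,
        expert_reviewed=bool(rng.random() < 0.3),
    )
    return GenPair(
        polygons=polygons,
        probability=probability,
        record_a=record_a,
        record_b=record_b,
        overlap_fraction_true=k / w,
        size_ratio_true=w_small / w,
        polygon_is_larger=polygon_is_larger,
        synonym_variant=variant,
    )


def gen_cohort(cfg: SimConfig) -> list[GenPair]:
    return [gen_range_pair(cfg, i) for i in range(cfg.n_species)]


def cohort_synonym_table(pairs: Iterable[GenPair]) -> SynonymTable:
    return SynonymTable(
        {p.synonym_variant[0]: p.synonym_variant[1] for p in pairs if p.synonym_variant}
    )


# ---------------------------------------------------------------------------
# bathymetry


def gen_bathymetry(cfg: SimConfig) -> tuple[BathymetryRaster, dict]:
    """Linear shelf: land west of coast_lon, depth = slope * offshore degrees.

    Per-cell depth is the minimum within the cell (its western edge, or 0
    for the cell straddling the shoreline). Ground truth records the
    analytic isobath longitudes, e.g. the 200 m isobath sits at
    coast_lon + 200 / slope degrees.
    """
    grid = cfg.grid
    res = grid.resolution_deg
    coast = cfg.coast_lon
    c_coast = (coast + 180.0) / res
    c_first = int(math.floor(c_coast))  # cell straddling (or starting at) the coast
    c_end = int(math.ceil((coast + cfg.shelf_extent_deg + 180.0) / res))
    depth: dict[Cell, float] = {}
    for c in range(c_first, min(c_end, grid.n_cols)):
        w_edge = -180.0 + c * res
        d = max(0.0, cfg.shelf_slope_m_per_deg * (w_edge - coast))
        for r in range(grid.n_rows):
            depth[(r, c)] = d
    truth = {
        "isobath_lon_200m": coast + 200.0 / cfg.shelf_slope_m_per_deg,
        "coast_lon": coast,
        "slope_m_per_deg": cfg.shelf_slope_m_per_deg,
    }
    return BathymetryRaster(grid, depth), truth


@dataclass(frozen=True)
class DrownedPair:
    """Expert range straddling the isobath, model range confined above it."""

    expert: PresenceRaster
    model: PresenceRaster
    drowned_fraction_true: float  # fraction of expert area below the limit


def gen_drowned_pairs(
    cfg: SimConfig, max_depth_m: float = 200.0
) -> tuple[list[DrownedPair], BathymetryRaster]:
    """Shallow-water pairs whose expert range extends below the depth limit.

    Each expert range is a block with a known fraction of its columns in
    water deeper than `max_depth_m` on the shelf; the paired model range is
    the shallow portion, so depth clipping removes only commission error
    (cells absent from the model range). The achieved drowned fraction is
    exact up to one column of rounding.
    """
    bathy, _ = gen_bathymetry(cfg)
    grid = cfg.grid
    res = grid.resolution_deg
    iso_lon = cfg.coast_lon + max_depth_m / cfg.shelf_slope_m_per_deg
    # first column whose minimum (west-edge) depth is >= limit
    col_limit = int(math.ceil((iso_lon + 180.0) / res))
    col_coast = int(math.ceil((cfg.coast_lon + 180.0) / res))
    max_shallow = col_limit - col_coast - 1  # columns of marine shelf above the limit
    if max_shallow < 2:
        raise ValueError("shelf too narrow above the depth limit for range placement")
    rng = _rng(cfg, 2)
    pairs = []
    h = cfg.rows_per_range
    for i in range(cfg.n_species):
        q = float(
            np.clip(cfg.drowned_fraction + rng.uniform(-cfg.cohort_spread, cfg.cohort_spread), 0.02, 0.95)
        )
        # build from the shallow side so the range never leaves the shelf
        n_shallow = int(rng.integers(2, max_shallow + 1))
        n_deep = max(1, int(round(q / (1.0 - q) * n_shallow)))
        max_deep = col_coast + int(cfg.shelf_extent_deg / res) - col_limit - 1
        n_deep = min(n_deep, max_deep)
        width = n_shallow + n_deep
        top = grid.n_rows // 2 + int(rng.integers(-15, 16)) - h // 2
        rows = range(top, top + h)
        cols = range(col_limit - n_shallow, col_limit + n_deep)
        expert = PresenceRaster(
            f"coral{i:04d}", grid, _rect_cells(rows, cols, grid.n_cols)
        )
        # model range: the shallow portion, occasionally a little narrower
        shrink = int(rng.integers(0, 3))
        shrink = min(shrink, (col_limit - cols.start) - 1)
        shallow_cols = range(cols.start + shrink, col_limit)
        model = PresenceRaster(
            f"coral{i:04d}", grid, _rect_cells(rows, shallow_cols, grid.n_cols)
        )
        pairs.append(DrownedPair(expert, model, n_deep / width))
    return pairs, bathy


# ---------------------------------------------------------------------------
# georegion truncation


@dataclass(frozen=True)
class TruncatedCohort:
    rasters: list[PresenceRaster]
    truncated_ids: frozenset[str]  # species planted with an edge on the meridian
    meridian: float
    band: tuple[float, float]
    domain: tuple[float, float]


def gen_truncated_ranges(cfg: SimConfig) -> TruncatedCohort:
    """Equatorial ranges, a planted fraction ending exactly at the meridian.

    Non-truncated species either stop short of the meridian by at least one
    cell or span across it by at least one cell; neither must be flagged by
    the coincidence scan. All ranges lie inside the 25S-20N band and the
    Indo-Pacific longitude domain (20E eastward to 140W).
    """
    grid = cfg.grid
    res = grid.resolution_deg
    band = (-25.0, 20.0)
    domain = (20.0, -140.0)
    m_col = int(round((cfg.truncation_meridian + 180.0) / res))  # edge index
    rng = _rng(cfg, 3)
    r_top_min = int((90.0 - band[1]) / res)        # first full row inside
    r_bot_max = int((90.0 - band[0]) / res) - 1    # last full row inside
    n_trunc = int(round(cfg.truncated_fraction * cfg.n_species))
    rasters, truncated = [], set()
    for i in range(cfg.n_species):
        h = int(rng.integers(4, 9))
        top = int(rng.integers(r_top_min, r_bot_max - h + 2))
        width = int(rng.integers(10, 40))
        is_trunc = i < n_trunc
        if is_trunc:
            end = m_col
        elif rng.random() < 0.5:
            end = m_col - int(rng.integers(1, 11))   # stops short
        else:
            end = m_col + int(rng.integers(1, 11))   # spans across
        cols = range(end - width, end)
        sid = f"t{i:04d}"
        rasters.append(
            PresenceRaster(sid, grid, _rect_cells(range(top, top + h), cols, grid.n_cols))
        )
        if is_trunc:
            truncated.add(sid)
    return TruncatedCohort(
        rasters, frozenset(truncated), cfg.truncation_meridian, band, domain
    )


# ---------------------------------------------------------------------------
# protected areas


@dataclass(frozen=True)
class ProtectionScene:
    """Fine marine/protected masks over a latitude window of the globe."""

    marine: np.ndarray      # 2D bool
    protected: np.ndarray   # 2D bool
    origin: Cell            # coarse cell at the window's top-left corner
    fine_resolution_deg: float
    protected_marine_fraction: float  # achieved, == target up to one fine cell


def gen_protection(cfg: SimConfig) -> ProtectionScene:
    """Patchy protected-area coverage with an exactly known marine fraction.

    The window spans latitudes 40N-40S at all longitudes. A rectangular
    land block breaks up the marine mask; square protected patches are
    placed at random until the configured fraction of marine fine cells is
    protected, the last patch trimmed so the count is exact.
    """
    grid = cfg.grid
    res = grid.resolution_deg
    factor = round(res / cfg.fine_resolution_deg)
    if abs(res / cfg.fine_resolution_deg - factor) > 1e-9:
        raise ValueError("fine resolution must nest evenly in the grid resolution")
    r0 = int((90.0 - 40.0) / res)
    n_rows_coarse = int(80.0 / res)
    shape = (n_rows_coarse * factor, grid.n_cols * factor)
    marine = np.ones(shape, dtype=bool)

    # land block: lon 100..140E, lat 0..40N (top half of the window)
    lon_a = int((100.0 + 180.0) / res) * factor
    lon_b = int((140.0 + 180.0) / res) * factor
    lat_a = 0
    lat_b = int(40.0 / res) * factor
    marine[lat_a:lat_b, lon_a:lon_b] = False

    protected = np.zeros(shape, dtype=bool)
    target = int(round(cfg.protection_fraction * marine.sum()))
    rng = _rng(cfg, 4)
    patch = 4 * factor  # 2-degree square patches
    placed = 0
    guard = 0
    while placed < target and guard < 100000:
        guard += 1
        i = int(rng.integers(0, shape[0] - patch))
        j = int(rng.integers(0, shape[1] - patch))
        block = marine[i : i + patch, j : j + patch] & ~protected[i : i + patch, j : j + patch]
        gain = int(block.sum())
        if gain == 0:
            continue
        if placed + gain <= target:
            protected[i : i + patch, j : j + patch] |= block
            placed += gain
        else:
            need = target - placed
            flat = np.flatnonzero(block.ravel())[:need]
            sub = np.zeros(block.size, dtype=bool)
            sub[flat] = True
            protected[i : i + patch, j : j + patch] |= sub.reshape(block.shape)
            placed = target
    achieved = protected.sum() / marine.sum()
    return ProtectionScene(
        marine, protected, (r0, 0), cfg.fine_resolution_deg, float(achieved)
    )
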