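"""Independent oracles used by the tests: dense point-sampling occupancy,
exhaustive edge scans, and brute-force block counting. These deliberately
avoid the code paths they check."""

from __future__ import annotations

import math

import numpy as np
import shapely

from rangealign.grid import GridSpec


def candidate_cells(grid: GridSpec, bounds) -> list[tuple[int, int]]:
    res = grid.resolution_deg
    lon0, lat0, lon1, lat1 = bounds
    c0 = max(0, int(math.floor((lon0 + 180.0) / res)))
    c1 = min(grid.n_cols - 1, int(math.ceil((lon1 + 180.0) / res)) - 1)
    r0 = max(0, int(math.floor((90.0 - lat1) / res)))
    r1 = min(grid.n_rows - 1, int(math.ceil((90.0 - lat0) / res)) - 1)
    return [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]


def mc_cell_fraction(
    poly, grid: GridSpec, cell: tuple[int, int], n: int, rng
) -> float:
    """Monte-Carlo estimate of the spherical fraction of a cell covered by
    `poly`: points are uniform on the sphere within the cell (longitude
    uniform, sine of latitude uniform)."""
    r, c = cell
    res = grid.resolution_deg
    lon_w = -180.0 + c * res
    lat_n = 90.0 - r * res
    lon = rng.uniform(lon_w, lon_w + res, n)
    s1, s2 = math.sin(math.radians(lat_n - res)), math.sin(math.radians(lat_n))
    lat = np.degrees(np.arcsin(rng.uniform(s1, s2, n)))
    shapely.prepare(poly)
    return float(np.mean(shapely.contains_xy(poly, lon, lat)))


def mc_occupancy(poly, grid: GridSpec, n: int, rng) -> dict[tuple[int, int], float]:
    """Point-sampling fractions for every candidate cell of a polygon."""
    return {
        cell: mc_cell_fraction(poly, grid, cell, n, rng)
        for cell in candidate_cells(grid, poly.bounds)
    }


def random_convex_polygon(rng, max_span_deg=3.0, lat_limit=65.0):
    """Convex hull of random points inside a random window, grid-unaligned."""
    lon0 = rng.uniform(-170.0, 170.0 - max_span_deg)
    lat0 = rng.uniform(-lat_limit, lat_limit - max_span_deg)
    pts = np.column_stack(
        [
            rng.uniform(lon0, lon0 + max_span_deg, 12),
            rng.uniform(lat0, lat0 + max_span_deg, 12),
        ]
    )
    return shapely.convex_hull(shapely.multipoints(pts))


def exhaustive_edge(occupied, grid: GridSpec, side: str, domain) -> float:
    """Brute-force outer-edge longitude over every occupied cell."""
    west, east = domain
    length = (east - west) % 360.0
    res = grid.resolution_deg
    best = None
    for (_, c) in occupied:
        w_edge = -180.0 + c * res
        u = (w_edge - west) % 360.0
        if u + res > length + 1e-9:
            continue
        v = u + res if side == "east" else u
        if best is None or (side == "east" and v > best) or (side == "west" and v < best):
            best = v
    assert best is not None
    lon = ((west + best + 180.0) % 360.0) - 180.0
    if side == "east" and abs(lon + 180.0) < 1e-9:
        lon = 180.0
    return lon


def brute_force_aggregation(marine, protected, factor):
    """Per-block protected fraction by explicit python loops."""
    n_r, n_c = marine.shape
    out = {}
    for i in range(n_r // factor):
        for j in range(n_c // factor):
            m = p = 0
            for a in range(factor):
                for b in range(factor):
                    if marine[i * factor + a, j * factor + b]:
                        m += 1
                        if protected[i * factor + a, j * factor + b]:
                            p += 1
            if m:
                out[(i, j)] = p / m
    return out
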