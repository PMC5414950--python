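"""Reading and writing the package's vector, table and raster dialects.

Vector input is GeoJSON (RFC 7946 FeatureCollection, lon-lat degrees) or a
tab-separated WKT text file; ESRI Shapefile is deliberately not parsed here
and is rejected with a conversion hint. Gridded data travel either as the
CSV triplet dialect (one row per stored cell, cell-center coordinates at
half-resolution offsets, floats with 6 significant digits) or as plain
north-up TIFF arrays whose georeferencing is implied by the GridSpec.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape

from .grid import GridError, GridSpec
from .polygons import GeometryError, RangePolygonSet
from .rasters import CoverageWeightRaster, PresenceRaster, ProbabilityRaster

__all__ = [
    "FormatError",
    "read_polygons",
    "read_probability_table",
    "write_probability_table",
    "read_presence",
    "write_presence",
    "read_cell_values",
    "write_cell_values",
    "read_raster_tif",
    "write_raster_tif",
]

_FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Malformed or unsupported input file."""


# ---------------------------------------------------------------------------
# vector input


def read_polygons(path: str | Path, fmt: str | None = None) -> list[RangePolygonSet]:
    """Read species range polygons from GeoJSON or WKT.

    GeoJSON features must carry a ``species_id`` property (``subpopulation``
    optional). The WKT dialect is one geometry per line:
    ``species_id<TAB>[subpopulation<TAB>]WKT``.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {
            ".geojson": "geojson",
            ".json": "geojson",
            ".wkt": "wkt",
            ".shp": "shapefile",
        }.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer vector format from {path.name!r}")
    if fmt == "shapefile":
        raise FormatError(
            "ESRI Shapefile input is not supported; convert to GeoJSON "
            "(e.g. `ogr2ogr -f GeoJSON out.geojson in.shp`) and retry"
        )
    if fmt == "geojson":
        return _read_geojson(path)
    if fmt == "wkt":
        return _read_wkt(path)
    raise FormatError(f"unknown vector format {fmt!r}")


def _read_geojson(path: Path) -> list[RangePolygonSet]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        features = doc.get("features", [])
    elif doc.get("type") == "Feature":
        features = [doc]
    else:
        raise FormatError(f"{path.name}: expected a GeoJSON Feature(Collection)")
    crs = doc.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", ""))
        if not name.endswith(("CRS84", "4326")):
            raise FormatError(f"{path.name}: unsupported CRS {name!r}; lon-lat only")
    out = []
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        sid = props.get("species_id")
        if sid is None:
            raise FormatError(f"{path.name}: feature {i} lacks a species_id property")
        try:
            geom = geojson_shape(feat["geometry"])
            out.append(
                RangePolygonSet.from_geometry(
                    str(sid), geom, props.get("subpopulation")
                )
            )
        except (KeyError, GeometryError, ValueError) as exc:
            raise FormatError(f"{path.name}: feature {i} ({sid}): {exc}") from exc
    return out


def _read_wkt(path: Path) -> list[RangePolygonSet]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                sid, sub, wkt = parts[0], None, parts[1]
            elif len(parts) == 3:
                sid, sub, wkt = parts
            else:
                raise FormatError(
                    f"{path.name}: line {lineno}: expected "
                    "species_id<TAB>[subpopulation<TAB>]WKT"
                )
            try:
                geom = shapely.from_wkt(wkt)
                out.append(RangePolygonSet.from_geometry(sid, geom, sub))
            except (shapely.errors.GEOSException, GeometryError) as exc:
                raise FormatError(f"{path.name}: line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# CSV triplet dialects


def _read_table(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path.name}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    return df


def _cells_from_centers(
    grid: GridSpec, df: pd.DataFrame, path: Path
) -> list[tuple[int, int]]:
    cells = []
    for idx, lon, lat in zip(df.index, df["center_lon"], df["center_lat"]):
        try:
            cells.append(grid.point_to_cell(float(lon), float(lat)))
        except (GridError, ValueError) as exc:
            raise FormatError(f"{path.name}: line {idx + 2}: {exc}") from exc
    return cells


def read_probability_table(
    path: str | Path, grid: GridSpec
) -> dict[str, ProbabilityRaster]:
    """Read per-cell occurrence probabilities (species_id, center_lon,
    center_lat, probability); returns one raster per species.

    Probabilities outside [0, 1] are errors reported with their line number;
    zero-probability rows are dropped (absence is implicit).
    """
    path = Path(path)
    df = _read_table(path, ("species_id", "center_lon", "center_lat", "probability"))
    bad = df[(df["probability"] < 0) | (df["probability"] > 1) | df["probability"].isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad.index[:5]]
        raise FormatError(
            f"{path.name}: probability outside [0, 1] at line(s) {lines}"
        )
    cells = _cells_from_centers(grid, df, path)
    per_species: dict[str, dict[tuple[int, int], float]] = {}
    for sid, cell, p in zip(df["species_id"].astype(str), cells, df["probability"]):
        if p > 0:
            per_species.setdefault(sid, {})[cell] = float(p)
    return {
        sid: ProbabilityRaster(sid, grid, vals) for sid, vals in per_species.items()
    }


def write_probability_table(
    rasters: Iterable[ProbabilityRaster], path: str | Path
) -> None:
    rows = []
    for ras in rasters:
        for (r, c) in sorted(ras.values):
            lon, lat = ras.grid.cell_center(r, c)
            rows.append((ras.species_id, lon, lat, ras.values[(r, c)]))
    df = pd.DataFrame(
        rows, columns=["species_id", "center_lon", "center_lat", "probability"]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_presence(path: str | Path, grid: GridSpec) -> dict[str, PresenceRaster]:
    """Read presence CSV (species_id, center_lon, center_lat)."""
    path = Path(path)
    df = _read_table(path, ("species_id", "center_lon", "center_lat"))
    cells = _cells_from_centers(grid, df, path)
    per_species: dict[str, set[tuple[int, int]]] = {}
    for sid, cell in zip(df["species_id"].astype(str), cells):
        per_species.setdefault(sid, set()).add(cell)
    return {
        sid: PresenceRaster(sid, grid, frozenset(cs))
        for sid, cs in per_species.items()
    }


def write_presence(rasters: Iterable[PresenceRaster], path: str | Path) -> None:
    rows = []
    for ras in rasters:
        for (r, c) in sorted(ras.occupied):
            lon, lat = ras.grid.cell_center(r, c)
            rows.append((ras.species_id, lon, lat))
    df = pd.DataFrame(rows, columns=["species_id", "center_lon", "center_lat"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cell_values(
    path: str | Path, grid: GridSpec, value_column: str
) -> dict[tuple[int, int], float]:
    """Read a single-layer cell-value CSV (center_lon, center_lat, <value>)."""
    path = Path(path)
    df = _read_table(path, ("center_lon", "center_lat", value_column))
    cells = _cells_from_centers(grid, df, path)
    return {
        cell: float(v) for cell, v in zip(cells, df[value_column]) if not np.isnan(v)
    }


def write_cell_values(
    values: dict[tuple[int, int], float],
    grid: GridSpec,
    path: str | Path,
    value_column: str,
) -> None:
    rows = []
    for (r, c) in sorted(values):
        lon, lat = grid.cell_center(r, c)
        rows.append((lon, lat, values[(r, c)]))
    df = pd.DataFrame(rows, columns=["center_lon", "center_lat", value_column])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# TIFF rasters (north-up, georeference implied by the GridSpec)


def write_raster_tif(array: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(array))


def read_raster_tif(path: str | Path, grid: GridSpec | None = None) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(str(path))
    if grid is not None and arr.shape != (grid.n_rows, grid.n_cols):
        raise FormatError(
            f"raster shape {arr.shape} does not match grid "
            f"({grid.n_rows}, {grid.n_cols})"
        )
    return arr
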