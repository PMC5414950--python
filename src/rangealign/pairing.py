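"""Pairing species mapped in both datasets and merging subpopulation maps.

Records are matched first on Red List identification codes where both
datasets carry one, and otherwise on genus-species binomials after
normalization through a user-supplied synonym table (no fuzzy matching:
reproducibility over recall). Each record joins at most one pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .grid import GridError
from .rasters import PresenceRaster

__all__ = [
    "Dataset",
    "SpeciesRecord",
    "SynonymTable",
    "PairedSpecies",
    "PairingError",
    "canonicalize",
    "pair_species",
    "merge_subpopulations",
    "read_species_table",
    "read_synonym_table",
]


class PairingError(ValueError):
    """Ambiguous or inconsistent pairing input."""


class Dataset(str, Enum):
    EXPERT_POLYGONS = "expert_polygons"
    MODEL_RASTER = "model_raster"


@dataclass(frozen=True)
class SpeciesRecord:
    """Metadata for one species in one dataset.

    `occurcells` is the count of unique grid cells holding validated
    occurrence records (a data-quality proxy); depth limits are meters,
    positive downward.
    """

    dataset: Dataset
    species_id: str
    binomial: str
    redlist_id: str | None = None
    occurcells: int | None = None
    occurrence_records: int | None = None
    expert_reviewed: bool = False
    depth_min_m: float | None = None
    depth_max_m: float | None = None

    def __post_init__(self) -> None:
        if not self.binomial or not self.binomial.strip():
            raise PairingError(f"record {self.species_id}: empty binomial")
        if self.occurcells is not None and self.occurcells < 0:
            raise PairingError(f"record {self.species_id}: negative occurcells")
        if (
            self.depth_min_m is not None
            and self.depth_max_m is not None
            and self.depth_min_m > self.depth_max_m
        ):
            raise PairingError(
                f"record {self.species_id}: depth_min exceeds depth_max"
            )


class SynonymTable:
    """Map from variant binomials to canonical binomials.

    Keys and values are normalized on construction; canonical names are
    fixed points of the map.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for variant, canonical in (mapping or {}).items():
            v = _normalize_binomial(variant)
            c = _normalize_binomial(canonical)
            if v != c:
                self._map[v] = c
        for canonical in list(self._map.values()):
            if canonical in self._map:
                raise PairingError(
                    f"synonym table canonical name {canonical!r} is itself mapped"
                )

    def resolve(self, normalized: str) -> str:
        return self._map.get(normalized, normalized)

    def __len__(self) -> int:
        return len(self._map)


def _normalize_binomial(binomial: str) -> str:
    words = binomial.strip().split()
    if not words:
        return ""
    lowered = [w.lower() for w in words]
    lowered[0] = lowered[0].capitalize()
    return " ".join(lowered)


def canonicalize(binomial: str, syn: SynonymTable | None = None) -> str:
    """Trim/case-normalize a binomial and resolve it through the synonym table."""
    norm = _normalize_binomial(binomial)
    if not norm:
        raise PairingError("empty binomial")
    return (syn or SynonymTable()).resolve(norm)


@dataclass(frozen=True)
class PairedSpecies:
    canonical_id: str
    record_a: SpeciesRecord
    record_b: SpeciesRecord
    match_basis: str  # "redlist_id" or "binomial"

    def __post_init__(self) -> None:
        if self.record_a.dataset == self.record_b.dataset:
            raise PairingError(
                f"pair {self.canonical_id}: records from the same dataset"
            )


def _index_by_redlist(
    records: Iterable[SpeciesRecord],
) -> dict[str, SpeciesRecord]:
    index: dict[str, SpeciesRecord] = {}
    dupes: dict[str, list[str]] = {}
    for rec in records:
        if rec.redlist_id is None:
            continue
        if rec.redlist_id in index:
            dupes.setdefault(rec.redlist_id, [index[rec.redlist_id].species_id]).append(
                rec.species_id
            )
        index[rec.redlist_id] = rec
    if dupes:
        detail = "; ".join(f"{rid}: {ids}" for rid, ids in sorted(dupes.items()))
        raise PairingError(f"duplicate redlist_id within one dataset — {detail}")
    return index


def pair_species(
    records_a: Iterable[SpeciesRecord],
    records_b: Iterable[SpeciesRecord],
    syn: SynonymTable | None = None,
) -> list[PairedSpecies]:
    """Match the two rosters into paired-map species.

    Red List id matches are resolved first and removed; remaining records
    match on canonicalized binomials. Residual one-to-many name matches are
    excluded with a warning. Output is sorted by canonical id.
    """
    a_list, b_list = list(records_a), list(records_b)
    syn = syn or SynonymTable()
    pairs: list[PairedSpecies] = []

    idx_a, idx_b = _index_by_redlist(a_list), _index_by_redlist(b_list)
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for rid in idx_a.keys() & idx_b.keys():
        ra, rb = idx_a[rid], idx_b[rid]
        pairs.append(PairedSpecies(str(rid), ra, rb, "redlist_id"))
        matched_a.add(ra.species_id)
        matched_b.add(rb.species_id)

    def by_name(records: list[SpeciesRecord], taken: set[str]):
        out: dict[str, list[SpeciesRecord]] = {}
        for rec in records:
            if rec.species_id in taken:
                continue
            out.setdefault(canonicalize(rec.binomial, syn), []).append(rec)
        return out

    names_a = by_name(a_list, matched_a)
    names_b = by_name(b_list, matched_b)
    for name in names_a.keys() & names_b.keys():
        cand_a, cand_b = names_a[name], names_b[name]
        if len(cand_a) > 1 or len(cand_b) > 1:
            warnings.warn(
                f"binomial {name!r} matches multiple records "
                f"({[r.species_id for r in cand_a + cand_b]}); excluded",
                stacklevel=2,
            )
            continue
        pairs.append(PairedSpecies(name, cand_a[0], cand_b[0], "binomial"))

    return sorted(pairs, key=lambda p: p.canonical_id)


def merge_subpopulations(rasters: Iterable[PresenceRaster]) -> PresenceRaster:
    """Union subpopulation maps of one species into a single global range."""
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no rasters to merge")
    first = rasters[0]
    occupied: set[tuple[int, int]] = set()
    for ras in rasters:
        if ras.species_id != first.species_id:
            raise PairingError(
                f"cannot merge {ras.species_id!r} into {first.species_id!r}"
            )
        if ras.grid != first.grid:
            raise GridError("subpopulation rasters on different grids")
        occupied |= ras.occupied
    return PresenceRaster(first.species_id, first.grid, frozenset(occupied))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_species_table(path: str | Path, dataset: Dataset) -> list[SpeciesRecord]:
    """Read a species roster CSV (species_id, binomial, optional redlist_id,
    occurcells, occurrence_records, expert_reviewed, depth_min_m, depth_max_m)."""
    df = pd.read_csv(path)
    for col in ("species_id", "binomial"):
        if col not in df.columns:
            raise PairingError(f"{Path(path).name}: missing column {col!r}")

    def opt(row, col, cast):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return cast(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesRecord(
                dataset=dataset,
                species_id=str(row["species_id"]),
                binomial=str(row["binomial"]),
                redlist_id=opt(row, "redlist_id", lambda v: str(int(v)) if isinstance(v, float) else str(v)),
                occurcells=opt(row, "occurcells", lambda v: int(v)),
                occurrence_records=opt(row, "occurrence_records", lambda v: int(v)),
                expert_reviewed=bool(opt(row, "expert_reviewed", lambda v: bool(v)) or False),
                depth_min_m=opt(row, "depth_min_m", float),
                depth_max_m=opt(row, "depth_max_m", float),
            )
        )
    return out


def read_synonym_table(path: str | Path) -> SynonymTable:
    df = pd.read_csv(path)
    for col in ("variant", "canonical"):
        if col not in df.columns:
            raise PairingError(f"{Path(path).name}: missing column {col!r}")
    return SynonymTable(dict(zip(df["variant"].astype(str), df["canonical"].astype(str))))


def write_pairs(pairs: Iterable[PairedSpecies], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "canonical_id": p.canonical_id,
                "species_id_a": p.record_a.species_id,
                "species_id_b": p.record_b.species_id,
                "match_basis": p.match_basis,
            }
            for p in pairs
        ]
    )
    df.to_csv(path, index=False)
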