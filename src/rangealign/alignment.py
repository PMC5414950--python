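"""Distribution-alignment and area-ratio statistics for paired range maps.

For each paired species let A_small and A_large be the areas (km^2) of the
smaller and larger range representation, regardless of source dataset, and
A_overlap the area of their cell-set intersection. The two headline
statistics are

    alpha_dist = 100 * A_overlap / A_large      (distribution alignment)
    alpha_area = 100 * A_small   / A_large      (area ratio)

which satisfy 0 <= alpha_dist <= alpha_area <= 100. A companion statistic,
``overlap_pct_of_smaller`` = 100 * A_overlap / A_small, expresses how much
of the *smaller* range lies inside the larger; it is not bounded by
alpha_area and is the convention under which cohort mean distribution
alignment can exceed mean area ratio. Both are reported; quadrant
classification uses alpha_dist.

Species are partitioned into four quadrants by comparing (alpha_dist,
alpha_area) against cohort means: well_aligned (both above), distribution_
aligned (only alpha_dist above), area_aligned (only alpha_area above),
poorly_aligned (neither). Boundary ties go upward/rightward.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .grid import GridError
from .pairing import SpeciesRecord
from .rasters import PresenceRaster, range_area_km2

__all__ = [
    "AlignmentError",
    "AlignmentResult",
    "QuadrantThresholds",
    "QuadrantLabel",
    "alignment",
    "classify_quadrant",
    "cohort_thresholds",
    "summarize_alignment",
    "data_quality_summary",
    "results_to_frame",
]


class AlignmentError(ValueError):
    """Undefined alignment (e.g. both rasters empty)."""


class QuadrantLabel(str, Enum):
    WELL_ALIGNED = "well_aligned"            # upper right
    DISTRIBUTION_ALIGNED = "distribution_aligned"  # upper left
    AREA_ALIGNED = "area_aligned"            # lower right
    POORLY_ALIGNED = "poorly_aligned"        # lower left


@dataclass(frozen=True)
class AlignmentResult:
    canonical_id: str
    area_small_km2: float
    area_large_km2: float
    area_overlap_km2: float
    alpha_dist: float
    alpha_area: float
    larger_dataset: str  # "a", "b" or "tie"

    @property
    def overlap_pct_of_smaller(self) -> float:
        """100 * A_overlap / A_small — share of the smaller range inside the larger."""
        return 100.0 * self.area_overlap_km2 / self.area_small_km2 if self.area_small_km2 else 0.0


@dataclass(frozen=True)
class QuadrantThresholds:
    dist_mean: float
    area_mean: float

    def __post_init__(self) -> None:
        for v in (self.dist_mean, self.area_mean):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"threshold {v} outside [0, 100]")


def alignment(
    pres_a: PresenceRaster, pres_b: PresenceRaster, canonical_id: str | None = None
) -> AlignmentResult:
    """Compute the alignment statistics for one paired species.

    Areas use geodesic cell areas; the overlap is the area of the
    intersection of the two occupied cell sets. An equal-area tie reports
    larger_dataset = "tie" (alpha_area is then exactly 100).
    """
    if pres_a.grid != pres_b.grid:
        raise GridError("paired rasters must share one grid")
    if not pres_a.occupied and not pres_b.occupied:
        raise AlignmentError(
            f"alignment undefined: both rasters empty for "
            f"{canonical_id or pres_a.species_id}"
        )
    import math

    area_a, area_b = range_area_km2(pres_a), range_area_km2(pres_b)
    overlap_cells = pres_a.occupied & pres_b.occupied
    areas = pres_a.grid.row_areas_km2()
    area_overlap = math.fsum(areas[r] for r, _ in overlap_cells)

    if area_a > area_b:
        larger, a_small, a_large = "a", area_b, area_a
    elif area_b > area_a:
        larger, a_small, a_large = "b", area_a, area_b
    else:
        larger, a_small, a_large = "tie", area_a, area_b
    return AlignmentResult(
        canonical_id=canonical_id or pres_a.species_id,
        area_small_km2=a_small,
        area_large_km2=a_large,
        area_overlap_km2=area_overlap,
        alpha_dist=100.0 * area_overlap / a_large,
        alpha_area=100.0 * a_small / a_large,
        larger_dataset=larger,
    )


def classify_quadrant(res: AlignmentResult, th: QuadrantThresholds) -> QuadrantLabel:
    upper = res.alpha_dist >= th.dist_mean
    right = res.alpha_area >= th.area_mean
    if upper and right:
        return QuadrantLabel.WELL_ALIGNED
    if upper:
        return QuadrantLabel.DISTRIBUTION_ALIGNED
    if right:
        return QuadrantLabel.AREA_ALIGNED
    return QuadrantLabel.POORLY_ALIGNED


def cohort_thresholds(results: Sequence[AlignmentResult]) -> QuadrantThresholds:
    """Unweighted cohort means of alpha_dist and alpha_area.

    These are outputs of the cohort, recomputed for every analysis, never
    constants.
    """
    if not results:
        raise AlignmentError("cannot take means of an empty cohort")
    return QuadrantThresholds(
        dist_mean=statistics.fmean(r.alpha_dist for r in results),
        area_mean=statistics.fmean(r.alpha_area for r in results),
    )


def results_to_frame(results: Sequence[AlignmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "canonical_id": r.canonical_id,
                "area_small_km2": r.area_small_km2,
                "area_large_km2": r.area_large_km2,
                "area_overlap_km2": r.area_overlap_km2,
                "alpha_dist": r.alpha_dist,
                "alpha_area": r.alpha_area,
                "overlap_pct_of_smaller": r.overlap_pct_of_smaller,
                "larger_dataset": r.larger_dataset,
            }
            for r in results
        ]
    )


def summarize_alignment(
    results: Sequence[AlignmentResult],
    groups: Mapping[str, str] | None = None,
    thresholds: QuadrantThresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """Cohort summary: overall and per-stratum means, quadrant shares, and
    per-quadrant fraction of species whose larger range comes from dataset a.

    Returns {"overall": one row per stratum (+ "all"), "quadrants": one row
    per quadrant with n, pct and frac_larger_a}.
    """
    if not results:
        raise AlignmentError("empty result list")
    th = thresholds or cohort_thresholds(results)

    def stratum_row(name: str, subset: Sequence[AlignmentResult]) -> dict:
        return {
            "stratum": name,
            "n": len(subset),
            "mean_alpha_dist": statistics.fmean(r.alpha_dist for r in subset),
            "mean_alpha_area": statistics.fmean(r.alpha_area for r in subset),
            "mean_overlap_pct_of_smaller": statistics.fmean(
                r.overlap_pct_of_smaller for r in subset
            ),
        }

    rows = [stratum_row("all", results)]
    if groups:
        by_group: dict[str, list[AlignmentResult]] = {}
        for r in results:
            by_group.setdefault(groups.get(r.canonical_id, "unassigned"), []).append(r)
        rows.extend(stratum_row(g, subset) for g, subset in sorted(by_group.items()))
    overall = pd.DataFrame(rows)

    quad_rows = []
    labels = {q: [] for q in QuadrantLabel}
    for r in results:
        labels[classify_quadrant(r, th)].append(r)
    for q in QuadrantLabel:
        members = labels[q]
        n = len(members)
        larger_a = sum(1 for r in members if r.larger_dataset == "a")
        quad_rows.append(
            {
                "quadrant": q.value,
                "n": n,
                "pct": 100.0 * n / len(results),
                "frac_larger_a": (larger_a / n) if n else float("nan"),
            }
        )
    return {"overall": overall, "quadrants": pd.DataFrame(quad_rows)}


def data_quality_summary(
    results: Sequence[AlignmentResult],
    records: Mapping[str, SpeciesRecord],
    th: QuadrantThresholds,
) -> pd.DataFrame:
    """Median occurrence-record and occurcell counts, poorly-aligned quadrant
    vs all other species, with missing metadata excluded and counted."""
    import warnings

    groups: dict[str, dict[str, list[float]]] = {
        "poorly_aligned": {"occurrence_records": [], "occurcells": []},
        "other": {"occurrence_records": [], "occurcells": []},
    }
    excluded = {"poorly_aligned": 0, "other": 0}
    missing_join = 0
    for r in results:
        key = (
            "poorly_aligned"
            if classify_quadrant(r, th) is QuadrantLabel.POORLY_ALIGNED
            else "other"
        )
        rec = records.get(r.canonical_id)
        if rec is None:
            missing_join += 1
            excluded[key] += 1
            continue
        any_missing = False
        for field in ("occurrence_records", "occurcells"):
            val = getattr(rec, field)
            if val is None:
                any_missing = True
            else:
                groups[key][field].append(float(val))
        if any_missing:
            excluded[key] += 1
    if missing_join:
        warnings.warn(f"{missing_join} result(s) had no metadata record", stacklevel=2)

    rows = []
    for key, vals in groups.items():
        rows.append(
            {
                "group": key,
                "n": sum(
                    1
                    for r in results
                    if (classify_quadrant(r, th) is QuadrantLabel.POORLY_ALIGNED)
                    == (key == "poorly_aligned")
                ),
                "median_occurrence_records": (
                    statistics.median(vals["occurrence_records"])
                    if vals["occurrence_records"]
                    else float("nan")
                ),
                "median_occurcells": (
                    statistics.median(vals["occurcells"])
                    if vals["occurcells"]
                    else float("nan")
                ),
                "n_excluded": excluded[key],
            }
        )
    return pd.DataFrame(rows)
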