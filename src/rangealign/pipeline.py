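"""End-to-end runs: simulate an input bundle, execute the stages, report.

A run is driven by a RunConfig (YAML key/value file or keyword arguments)
and proceeds pairing -> alignment -> optional depth clip -> optional
boundary scan -> optional MPA gap analysis, writing per-stage CSV outputs,
a machine-readable manifest (inputs, parameters, software version, seed)
and a log. Stage failures abort with a stage-tagged message and the
manifest marks the run as partial. Identical configs produce identical
output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .alignment import (
    alignment,
    cohort_thresholds,
    data_quality_summary,
    results_to_frame,
    summarize_alignment,
)
from .boundary import BoundaryMeridian, LatBand, boundary_coincidence
from .grid import GridSpec, make_grid
from .habitat import build_depth_mask, clip_presence, eliminated_fraction, reclassification_table
from .io import (
    read_cell_values,
    read_polygons,
    read_presence,
    read_probability_table,
    read_raster_tif,
    write_presence,
    write_raster_tif,
)
from .habitat import BathymetryRaster
from .mpa import aggregate_protection, protected_fraction, protection_cohort_summary
from .pairing import (
    Dataset,
    merge_subpopulations,
    pair_species,
    read_species_table,
    read_synonym_table,
    write_pairs,
)
from .polygons import RangePolygonSet, polygon_cell_weights, rasterize_polygons
from .rasters import threshold_presence
from .synthetic import (
    SimConfig,
    gen_bathymetry,
    gen_cohort,
    gen_drowned_pairs,
    gen_protection,
    gen_truncated_ranges,
)

__all__ = ["RunConfig", "StageError", "run_pipeline", "write_bundle"]

log = logging.getLogger("rangealign")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    All referenced input files must exist at load time. `thresholds` are
    the probability presence thresholds evaluated for the model dataset
    (0 means any non-zero probability).
    """

    polygons_path: str
    probability_path: str
    species_a_path: str
    species_b_path: str
    out_dir: str
    synonyms_path: str | None = None
    bathymetry_path: str | None = None
    coral_expert_path: str | None = None
    coral_model_path: str | None = None
    scan_presence_path: str | None = None
    marine_mask_path: str | None = None
    protection_path: str | None = None
    resolution_deg: float = 0.5
    thresholds: list[float] = field(default_factory=lambda: [0.5, 0.0])
    alignment_threshold: float = 0.0
    depth_limit_m: float = 200.0
    band: tuple[float, float] | None = None
    meridians: list[float] = field(default_factory=list)
    scan_domain: tuple[float, float] = (20.0, -140.0)
    fine_resolution_deg: float = 0.1
    protection_origin_row: int = 0
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = RunConfig(**raw)
        except TypeError as exc:
            raise StageError(f"config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in (
            "polygons_path",
            "probability_path",
            "species_a_path",
            "species_b_path",
            "synonyms_path",
            "bathymetry_path",
            "coral_expert_path",
            "coral_model_path",
            "scan_presence_path",
            "marine_mask_path",
            "protection_path",
        ):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise StageError(f"config: input file for {name} not found: {val}")
        for t in self.thresholds:
            if not (0.0 <= t <= 1.0):
                raise StageError(f"config: threshold {t} outside [0, 1]")
        if self.band is not None:
            lo, hi = self.band
            if not (-90.0 <= lo < hi <= 90.0):
                raise StageError(f"config: invalid band {self.band}")


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "software": "rangealign",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.endswith("_path")
        },
        "inputs": {
            k: {"path": v, "sha256_16": _file_digest(v)}
            for k, v in asdict(config).items()
            if k.endswith("_path") and v is not None
        },
        "outputs": [],
        "complete": False,
    }

    def emit(name: str) -> Path:
        manifest["outputs"].append(name)
        return out / name

    grid = make_grid(config.resolution_deg)
    stage = "load"
    try:
        records_a = read_species_table(config.species_a_path, Dataset.EXPERT_POLYGONS)
        records_b = read_species_table(config.species_b_path, Dataset.MODEL_RASTER)
        syn = read_synonym_table(config.synonyms_path) if config.synonyms_path else None
        poly_sets = read_polygons(config.polygons_path)
        prob = read_probability_table(config.probability_path, grid)

        stage = "pairing"
        pairs = pair_species(records_a, records_b, syn)
        log.info("pairing: %d paired species", len(pairs))
        write_pairs(pairs, emit("pairs.csv"))

        stage = "rasterize"
        by_species: dict[str, list] = {}
        for ps in poly_sets:
            by_species.setdefault(ps.species_id, []).append(ps)
        presence_a = {
            sid: merge_subpopulations([rasterize_polygons(p, grid) for p in parts])
            for sid, parts in by_species.items()
        }
        presence_b = {
            sid: threshold_presence(p, config.alignment_threshold)
            for sid, p in prob.items()
        }

        stage = "alignment"
        results, skipped = [], 0
        for pr in pairs:
            pa = presence_a.get(pr.record_a.species_id)
            pb = presence_b.get(pr.record_b.species_id)
            if pa is None or pb is None or (not pa.occupied and not pb.occupied):
                skipped += 1
                continue
            results.append(alignment(pa, pb, pr.canonical_id))
        if not results:
            raise StageError("alignment: no pair had any mapped cells")
        log.info("alignment: %d results (%d skipped)", len(results), skipped)
        th = cohort_thresholds(results)
        results_to_frame(results).to_csv(emit("alignment.csv"), index=False)
        summary = summarize_alignment(results, thresholds=th)
        summary["overall"].to_csv(emit("alignment_summary.csv"), index=False)
        summary["quadrants"].to_csv(emit("alignment_quadrants.csv"), index=False)
        meta = {
            pr.canonical_id: pr.record_b for pr in pairs
        }
        data_quality_summary(results, meta, th).to_csv(
            emit("data_quality.csv"), index=False
        )

        if config.bathymetry_path and config.coral_expert_path and config.coral_model_path:
            # depth audit of the shallow-water (coral-like) sub-cohort
            stage = "clip-depth"
            depth = read_cell_values(config.bathymetry_path, grid, "depth_m")
            mask = build_depth_mask(BathymetryRaster(grid, depth), config.depth_limit_m)
            coral_expert = read_presence(config.coral_expert_path, grid)
            coral_model = read_presence(config.coral_model_path, grid)
            clipped = {sid: clip_presence(p, mask) for sid, p in coral_expert.items()}
            elim_rows = [
                {
                    "species_id": sid,
                    "eliminated_pct": eliminated_fraction(coral_expert[sid], clipped[sid]),
                }
                for sid in sorted(coral_expert)
                if coral_expert[sid].occupied
            ]
            pd.DataFrame(elim_rows).to_csv(emit("depth_eliminated.csv"), index=False)
            coral_before, coral_after = [], []
            for sid in sorted(coral_expert):
                pm = coral_model.get(sid)
                if pm is None:
                    continue
                coral_before.append(alignment(coral_expert[sid], pm, sid))
                coral_after.append(alignment(clipped[sid], pm, sid))
            th_coral = cohort_thresholds(coral_before)
            trans, membership = reclassification_table(coral_before, coral_after, th_coral)
            trans.to_csv(emit("quadrant_transitions.csv"))
            membership.to_csv(emit("quadrant_membership.csv"), index=False)
            log.info(
                "clip-depth: mean eliminated %.1f%% over %d species",
                pd.DataFrame(elim_rows)["eliminated_pct"].mean(),
                len(elim_rows),
            )

        if config.band is not None and config.meridians:
            stage = "scan-boundaries"
            band = LatBand(*config.band)
            meridians = [BoundaryMeridian(m) for m in config.meridians]
            if config.scan_presence_path:
                scan_rasters = list(read_presence(config.scan_presence_path, grid).values())
            else:
                scan_rasters = list(presence_b.values())
            hits = boundary_coincidence(
                scan_rasters, band, meridians, "east", config.scan_domain
            )
            pd.DataFrame(
                [
                    {
                        "species_id": h.species_id,
                        "side": h.side,
                        "meridian": h.meridian.longitude,
                        "cells_at_edge": h.cells_at_edge,
                    }
                    for h in hits
                ]
            ).to_csv(emit("boundary_hits.csv"), index=False)
            log.info("scan-boundaries: %d species flagged", len(hits))

        if config.protection_path and config.marine_mask_path:
            stage = "mpa-gap"
            marine = read_raster_tif(config.marine_mask_path).astype(bool)
            protected = read_raster_tif(config.protection_path).astype(bool)
            prot = aggregate_protection(
                marine,
                protected,
                config.fine_resolution_deg,
                grid,
                origin=(config.protection_origin_row, 0),
            )
            scenarios: dict[str, list] = {}
            for t in config.thresholds:
                name = f"model_t{t:g}"
                scenarios[name] = [
                    protected_fraction(p, prot)
                    for p in (
                        threshold_presence(pr, t) for pr in prob.values()
                    )
                    if p.occupied
                ]
            weight_rasters = []
            for sid, parts in sorted(by_species.items()):
                merged = RangePolygonSet(
                    sid, tuple(pp for part in parts for pp in part.polygons)
                )
                ws = polygon_cell_weights(merged, grid)
                if ws.weights:
                    weight_rasters.append(ws)
            scenarios["expert_weights"] = [
                protected_fraction(w, prot) for w in weight_rasters
            ]
            protection_cohort_summary(scenarios).to_csv(
                emit("mpa_gap_summary.csv"), index=False
            )
    except StageError:
        _write_manifest(out, manifest)
        raise
    except Exception as exc:
        _write_manifest(out, manifest)
        raise StageError(f"{stage}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest["complete"] = True
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# simulate: write a complete input bundle + ground-truth sidecars


def write_bundle(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Generate all synthetic inputs into a directory, with ground truth.

    Writes the polygon GeoJSON, probability/species/synonym CSVs,
    bathymetry CSV, fine marine/protection TIFF masks, truncated-range
    presence CSV, a ready-to-run pipeline config, and ground-truth sidecar
    CSVs (one per generator).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = gen_cohort(cfg)
    grid = cfg.grid

    features = []
    for p in pairs:
        geom = p.polygons.union()
        features.append(
            {
                "type": "Feature",
                "properties": {"species_id": p.polygons.species_id},
                "geometry": json.loads(shapely.to_geojson(geom)),
            }
        )
    with open(out / "polygons.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    from .io import write_probability_table

    write_probability_table([p.probability for p in pairs], out / "probability.csv")

    def record_row(rec):
        return {
            "species_id": rec.species_id,
            "binomial": rec.binomial,
            "redlist_id": rec.redlist_id,
            "occurcells": rec.occurcells,
            "occurrence_records": rec.occurrence_records,
            "expert_reviewed": rec.expert_reviewed,
            "depth_min_m": rec.depth_min_m,
            "depth_max_m": rec.depth_max_m,
        }

    pd.DataFrame([record_row(p.record_a) for p in pairs]).to_csv(
        out / "species_a.csv", index=False
    )
    pd.DataFrame([record_row(p.record_b) for p in pairs]).to_csv(
        out / "species_b.csv", index=False
    )
    syn_rows = [
        {"variant": p.synonym_variant[0], "canonical": p.synonym_variant[1]}
        for p in pairs
        if p.synonym_variant
    ]
    pd.DataFrame(syn_rows, columns=["variant", "canonical"]).to_csv(
        out / "synonyms.csv", index=False
    )

    bathy, bathy_truth = gen_bathymetry(cfg)
    from .io import write_cell_values

    write_cell_values(bathy.depth_m, grid, out / "bathymetry.csv", "depth_m")

    scene = gen_protection(cfg)
    write_raster_tif(scene.marine.astype(np.uint8), out / "marine_mask.tif")
    write_raster_tif(scene.protected.astype(np.uint8), out / "protection.tif")

    trunc = gen_truncated_ranges(cfg)
    write_presence(trunc.rasters, out / "truncated_ranges.csv")

    drowned, _ = gen_drowned_pairs(cfg)
    write_presence([d.expert for d in drowned], out / "coral_expert.csv")
    write_presence([d.model for d in drowned], out / "coral_model.csv")

    # ground-truth sidecars
    pd.DataFrame(
        [
            {
                "species_id_a": p.record_a.species_id,
                "species_id_b": p.record_b.species_id,
                "overlap_fraction_true": p.overlap_fraction_true,
                "size_ratio_true": p.size_ratio_true,
                "polygon_is_larger": p.polygon_is_larger,
            }
            for p in pairs
        ]
    ).to_csv(out / "truth_pairs.csv", index=False)
    pd.DataFrame([bathy_truth]).to_csv(out / "truth_bathymetry.csv", index=False)
    pd.DataFrame(
        [
            {"species_id": r.species_id, "truncated": r.species_id in trunc.truncated_ids}
            for r in trunc.rasters
        ]
    ).to_csv(out / "truth_truncation.csv", index=False)
    pd.DataFrame(
        [{"protected_marine_fraction": scene.protected_marine_fraction}]
    ).to_csv(out / "truth_protection.csv", index=False)
    pd.DataFrame(
        [
            {
                "species_id": d.expert.species_id,
                "drowned_fraction_true": d.drowned_fraction_true,
            }
            for d in drowned
        ]
    ).to_csv(out / "truth_drowned.csv", index=False)

    run_cfg = {
        "polygons_path": str(out / "polygons.geojson"),
        "probability_path": str(out / "probability.csv"),
        "species_a_path": str(out / "species_a.csv"),
        "species_b_path": str(out / "species_b.csv"),
        "synonyms_path": str(out / "synonyms.csv"),
        "bathymetry_path": str(out / "bathymetry.csv"),
        "coral_expert_path": str(out / "coral_expert.csv"),
        "coral_model_path": str(out / "coral_model.csv"),
        "scan_presence_path": str(out / "truncated_ranges.csv"),
        "marine_mask_path": str(out / "marine_mask.tif"),
        "protection_path": str(out / "protection.tif"),
        "out_dir": str(out / "results"),
        "resolution_deg": grid.resolution_deg,
        "thresholds": [0.5, 0.0],
        "alignment_threshold": 0.5,
        "depth_limit_m": 200.0,
        "band": [-25.0, 20.0],
        "meridians": [cfg.truncation_meridian],
        "fine_resolution_deg": cfg.fine_resolution_deg,
        "protection_origin_row": scene.origin[0],
        "seed": cfg.seed,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return out
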