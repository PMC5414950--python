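# rangealign

Alignment auditing for paired marine species range maps.

Global marine species distributions come in two very different flavours:
expert-drawn **extent-of-occurrence polygons** (an outer envelope enclosing
all known occurrences) and **model-generated habitat-suitability rasters**
(a relative probability of occurrence per grid cell). Both claim to answer
"where does this species live?", yet for the same species they routinely
disagree — expert maps over-predict into unsuitable habitat (commission
error), while model maps can end abruptly at administrative ocean-region
borders rather than ecological limits. `rangealign` puts both products on a
common global equal-angle grid (0.5° by default) and quantifies exactly how,
and why, they disagree — and what the choice of product does to downstream
conservation results such as marine-protected-area (MPA) gap analyses.

## What it computes

For each species mapped in both datasets, with `A_small` and `A_large` the
areas (km², geodesic) of the smaller and larger range representation and
`A_overlap` the area of their cell-set intersection:

- **distribution alignment** `α_dist = 100 · A_overlap / A_large`
- **area ratio** `α_area = 100 · A_small / A_large`

so `0 ≤ α_dist ≤ α_area ≤ 100`. A companion statistic,
`overlap_pct_of_smaller = 100 · A_overlap / A_small`, reports how much of the
*smaller* range sits inside the larger one (the convention under which a
cohort's mean distribution alignment can exceed its mean area ratio). Species
are classified into four quadrants by comparing `(α_dist, α_area)` against
the cohort means: well-aligned, distribution-aligned, area-aligned, and
poorly-aligned.

Around that core the package provides:

- polygon rasterization with the *any-overlap* presence rule (a cell is
  present if the polygon covers any positive area of it) and fractional
  polygon coverage weights per cell;
- probability thresholding (`p ≥ t` for `t > 0`, `p > 0` at `t = 0`);
- species pairing by Red List id with binomial + synonym-table fallback, and
  subpopulation merging;
- depth clipping of ranges against a bathymetry (keep cells whose minimum
  depth is shallower than a species' depth limit) with eliminated-area and
  quadrant-reclassification reporting;
- a boundary scan that flags species whose range edge inside a latitude band
  coincides *exactly* with a georegion boundary meridian, plus the
  extrapolation-rate metric (km² of range per occurrence cell);
- MPA gap analysis: fine protected-area masks aggregated to per-cell marine
  protection fractions, per-species protected range percentages, and
  gap/<2%/2–5%/5–10%/≥10% protection bins;
- a synthetic-data generator that emulates all of the above with known
  ground truth (controllable overlap fraction, size ratio, shelf bathymetry,
  meridian truncation, patchy protection).

## Worked example

```sh
rangealign simulate --out bundle --seed 7 --n-species 50
rangealign run --config bundle/run_config.yaml
```

generates a complete synthetic input bundle (polygons, probability tables,
species rosters, synonyms, bathymetry, protection masks, plus ground-truth
sidecars) and runs pairing → alignment → depth clip → boundary scan → MPA
gap. From the library, the core computation looks like:

```python
from rangealign import make_grid, rasterize_polygons, threshold_presence, alignment
from rangealign.synthetic import SimConfig, gen_range_pair

cfg = SimConfig(seed=7, overlap_fraction=0.5, size_ratio=0.8, cohort_spread=0.0)
pair = gen_range_pair(cfg, 0)
pres_a = rasterize_polygons(pair.polygons, cfg.grid)       # expert polygons
pres_b = threshold_presence(pair.probability, 0.5)         # model footprint
res = alignment(pres_a, pres_b)
print(f"alpha_dist={res.alpha_dist:.1f} alpha_area={res.alpha_area:.1f}")
```

prints

```
alpha_dist=50.0 alpha_area=80.0
```

— the generator planted a pair whose thresholded model footprint overlaps
the polygon range by 50% of the larger range with a 0.8 area ratio, and the
pipeline measures exactly those values back. On the default cohort
conditions (size ratio 0.548, overlap 0.35 of the larger range) the cohort
means come out near `mean α_area ≈ 54.5` and `mean overlap-of-smaller ≈ 64.7`,
matching the alignment level typical of paired global range products.

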