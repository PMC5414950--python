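# Methods

## Grid model

All analyses live on a global equal-angle (plate carrée) grid covering
[−180, 180] × [−90, 90]. The resolution must divide 180 evenly; the default
0.5° matches the native resolution of global marine habitat-suitability
products. Row 0 abuts 90 N and column 0 abuts 180 W; cell (r, c) spans
`lon ∈ [−180 + c·res, −180 + (c+1)·res)` and `lat ∈ (90 − (r+1)·res, 90 − r·res]`.
The half-open convention maps every point to exactly one cell; the two
boundary cases a finite domain forces are lon = 180 (identified with −180)
and lat = −90 (clamped into the southernmost row).

Cell areas are geodesic on a sphere of authalic radius R = 6371 km via the
spherical-zone formula `R²·Δλ·(sin φ_top − sin φ_bot)`; they depend only on
the row. A sphere rather than an ellipsoid keeps per-row areas closed-form
and testable (the row areas sum to 4πR² to machine precision); the ~0.1%
departure from ellipsoidal areas is far below the discretization error of a
0.5° presence grid. Range areas sum cell areas with order-independent exact
float summation (`math.fsum`) so equal cell sets always give bit-equal
areas — this matters when deciding which of two ranges is "larger".

## Rasterization and coverage weights

Cell membership is decided by planar polygon–rectangle intersection in
lon-lat space: a cell is present iff the intersection area is strictly
positive (threshold 1e−12 deg², about 1e−2 m²). Boundary-only contact —
shared edges or vertices — is measure-zero and does not confer presence. A
polygon covering 1% of a cell marks it present: the any-overlap rule is
deliberately generous, mirroring how extent-of-occurrence envelopes are
meant to be read. Edges are treated as straight segments in the equal-angle
plane, which is consistent with gridding data natively published on that
grid; whether the original polygon overlays were planar or spherical is not
decidable from published descriptions, and sliver-case differences near the
poles are documented rather than guessed away.

Coverage weights are the fraction of a cell's *spherical* area covered:
the planar intersection geometry is pushed through the cylindrical
equal-area transform (λ, sin φ), under which planar area × R² is the exact
spherical area for any region bounded by meridian/parallel segments.
Oblique edges are densified to 0.05° before the transform, bounding the
chord error at ~1e−5 relative for 0.5° cells — the tests hold weights to a
dense spherical Monte-Carlo oracle within 0.01 and the weight-area sum to
an independently computed whole-polygon spherical area within 0.5%.

Antimeridian handling: a geometry's 360°-longitude translates are clipped
to the world box and unioned, so ranges expressed on a 0–360 convention or
crossing 180° rasterize identically to their wrapped equivalents (a tested
invariant). Invalid rings are repaired by zero-width buffering; irreparable
or empty geometries are errors, never silently dropped.

## Probability thresholds

`threshold_presence(p, t)` keeps cells with `p ≥ t` when `t > 0` (the
"50% or greater" reading used in protection scenarios) and cells with
`p > 0` when `t = 0` (the "any non-zero probability" reading that turns a
suitability raster into an extent of occurrence). The two boundary
semantics genuinely differ, hence the explicit split. Presence is monotone
non-increasing in `t` (property-tested).

## Pairing

Rosters are matched first on Red List identification codes present in both
datasets, then by genus-species binomial after whitespace/case
normalization and a user-supplied synonym table (replacing live taxonomic
web services; reproducibility over recall, so no fuzzy matching). Duplicate
ids within one dataset are an ambiguity error listing the offenders;
residual one-to-many binomial matches are warned about and excluded, since
how such conflicts were reconciled historically is not documented anywhere
authoritative. Subpopulation maps are merged by cell-set union before
comparison. Pairing is symmetric and no record joins two pairs (tested).

## Alignment statistics and quadrants

With A_small, A_large the smaller/larger range areas and A_overlap the
intersection area, the package reports `α_dist = 100·A_overlap/A_large` and
`α_area = 100·A_small/A_large`, which satisfy
`0 ≤ α_dist ≤ α_area ≤ 100` for every species. It also reports
`overlap_pct_of_smaller = 100·A_overlap/A_small` — the share of the smaller
range contained in the larger. The two overlap conventions answer different
questions: the large-denominator form measures mutual concurrence of the
two footprints, the small-denominator form measures nestedness, and only
under the latter can a cohort's mean "distribution alignment" exceed its
mean area ratio (as it does for real paired range products, where small
model ranges often nest inside generous expert envelopes). Both are carried
through all outputs; quadrant classification uses `α_dist`.

Quadrant thresholds are the unweighted arithmetic cohort means of the two
statistics — outputs recomputed per cohort, never constants. Boundary ties
classify upward/rightward (≥). Species for which both rasters are empty
have undefined statistics; they are excluded and counted rather than
imputed. Equal-area ties set `larger_dataset = "tie"` with `α_area = 100`.

## Depth clipping

A bathymetry raster stores the minimum water depth per marine cell
(meters, positive downward; land/no-data cells are absent; finer inputs are
aggregated by block minimum). A depth mask at limit D keeps cells strictly
shallower than D: any shallow sliver keeps a cell, mirroring the generosity
of the any-overlap presence rule. Clipping intersects a presence raster
with the mask; the eliminated fraction is the percent of pre-clip area
removed. Re-quadranting after clipping holds thresholds frozen at the
pre-clip cohort means so movement is measured against the same boundaries.
When clipping removes only cells absent from the smaller range (pure
commission error), overlap is unchanged and `α_dist` cannot decrease — an
invariant asserted on generator cases built that way.

## Boundary scan

Ranges are cropped to a latitude band (whole cell rows only; the default
band 25 S–20 N falls on 0.5° grid lines so no partial rows arise), then the
eastern or western range edge is taken within a caller-supplied longitude
domain — a directed interval traversed eastward (default Indo-Pacific,
20 E → 140 W) whose own seam is excluded, removing the wrap ambiguity of a
circular coordinate. Edges are cell-edge longitudes, never centers, and
"coincides with a boundary meridian" means exact grid-line equality (1e−9°,
i.e. exact for grid-aligned meridians), not a tolerance window: a species
ending one cell short, or spanning one cell past, is not flagged. The
extrapolation-rate metric (range km² per occurrence cell) is a plain ratio,
undefined below one occurrence cell.

## MPA gap analysis

Fine boolean marine and protected masks (any resolution nesting evenly in
the grid; the real-world convention is 0.01°, the bundled generator uses
0.1° to keep global arrays small) are aggregated per coarse cell as
protected-marine over marine fine-cell counts — fractions are of the marine
portion of a cell, not total cell area, so a coastal cell half-full of land
is not diluted. Per species,
`protected_pct = 100·Σ w·f·A / Σ w·A` over occupied cells, with f the
cell's protection fraction, A its geodesic area (a cell-count mode is
available), and w either 1 (binary presence) or the polygon coverage weight
(the default for expert-polygon inputs, honouring fractional occupancy).
Gap status is exact: a species is a gap species iff no occupied cell has
positive protection. Bins are gap / (0,2) / [2,5) / [5,10) / [10,100]
percent, compared with a 1e−9 tolerance so exact boundary values are not
demoted by float noise; "<5% protected" cohort figures are the sum of the
first three bins. For fixed probability rasters, lowering the presence
threshold enlarges ranges and can only lose gap status (tested
monotonicity).

## Synthetic data

The generator is first-class, tested code, and defines the study
conditions. Ranges are grid-aligned rectangular blocks spanning a fixed set
of rows, grown combinatorially so the planted overlap fraction and size
ratio are achieved exactly up to one column of rounding — because both
members of a pair span the same rows, per-row areas cancel and area ratios
reduce to column-count ratios, making parameter recovery exact rather than
statistical. Default cohort conditions: size ratio 0.548 and overlap 0.35
of the larger range (equivalently ≈0.64 of the smaller), the alignment
level observed between global expert and model range products; per-species
uniform jitter of ±0.18 supplies cohort spread. Probabilities inside the
model footprint decay linearly from the habitat centroid within [0.55, 1]
(so the t = 0.5 footprint is exactly the planted cell set) and drop to
0.25/0.10 in a two-cell fringe (so t = 0 strictly widens the range); the
decay law is a documented constant, not tuned. Occurrence-cell counts
follow a lognormal law (log-mean 3.0, log-sd 1.2: median ≈ 20 cells, heavy
right tail, a realistic occurrence-effort distribution).

The shelf bathymetry is linear: land west of the coast meridian, depth
increasing eastward at 20 m/deg over 60°, so the 200 m isobath sits
analytically 10° offshore. The drowned-range cohort plants a known fraction
(default 0.478) of each expert range below the limit with the paired model
range confined to the shallow side, so depth clipping removes pure
commission error. The truncation cohort plants a fraction (default 0.3) of
equatorial ranges ending exactly at the boundary meridian (default 175 W),
with the rest stopping short or crossing past by at least one cell. The
protection scene covers 40 N–40 S at 0.1° with a land block, and places 2°
square protected patches until exactly the configured fraction (default
0.02) of marine fine cells is protected, trimming the last patch to hit the
count exactly. All generators are deterministic per (config, seed) and the
`simulate` command writes ground-truth sidecar CSVs beside the inputs.

What the generator does **not** emulate: real coastline geometry and
fragmented multi-part ranges, latitudinal richness gradients, spatial
autocorrelation of suitability beyond the radial decay, correlated errors
between the two datasets, and ellipsoidal geodesy. Passing tests therefore
demonstrate correctness of the pipeline's accounting — not that any real
dataset pair will show particular alignment values.

## Numerical choices

Positive-area rasterization threshold 1e−12 deg²; coverage-weight
densification 0.05°; longitude/meridian comparisons at 1e−9°; protection
bin edges at 1e−9; exact float summation for areas; all randomness through
`numpy.random.default_rng` seed sequences keyed by (seed, stage, index).
Problem sizes in the test and acceptance runs (cohorts of 40–300 species,
300–400-cell ranges, 100-polygon oracle batches at 10⁴ sample points per
cell, 0.1° fine masks) were chosen so each check runs in seconds while
keeping discretization error well inside the stated tolerances.

## Known limitations

Planar membership tests can differ from spherical ones in sliver cases
near the poles. Shapefile input is not parsed (convert to GeoJSON); TIFF
rasters are plain north-up arrays whose georeferencing is implied by the
grid, not tagged GeoTIFF. No reprojection: inputs must be lon-lat degrees.
The boundary scan only handles meridional (straight north-south) borders.
Protected-area category filtering is assumed to have happened upstream;
the package consumes an already-filtered protection layer.
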