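# Methods

This note records the modeling choices, parameter defaults, numerical
details and known limitations of the `ecoserv` pipeline, in the order the
stages run.

## Raster model

All maps are single-band rectangular grids (`RasterGrid`) with a square
cell size in meters, a world origin at the outer corner of the top-left
cell, and a nodata sentinel (default −9999). Indexing is (row, col) with
row 0 at the top; world coordinates refer to cell centers. Nodata
propagates: any cell invalid in any input of a multi-raster operation is
invalid in the output, and every such operation first checks that shapes,
cell sizes and origins agree exactly. No CRS handling is attempted —
reprojection belongs upstream of this pipeline. GeoTIFF I/O carries the
pixel-scale, tie-point and GDAL nodata tags; ESRI ASCII grids are the
text format used for fixtures and archives.

## Synthetic landscapes

The generator produces the study conditions the models assume, not a
replica of any real geography.

* **DEM** — the sum of `n_ridges` (default 4) Gaussian crests around random
  lines plus a low-pass Gaussian random field, rescaled exactly to
  `elevation_range` (default 586–2087 m). Deterministic under
  `(spec, seed)`.
* **LULC** — ten classes with default proportions matching the emulated
  region's composition (forest 44.5%, Cerrado 14.8%, pasture 13.8%,
  rupestrian grassland 9.6%, urban 6.7%, eucalyptus 4.9%, mining 2.9%,
  roads 1.9%, water 0.7%, agriculture 0.2%; habitat classes total 69.6%).
  Non-road classes grow from affinity-seeded nuclei by capacity-constrained
  multi-source region growing on a score field (elevation-preference
  penalty + smooth noise): quotas are exact by construction, patches are
  contiguous but irregular, threats intersperse with habitat. Elevation
  preferences put rupestrian grassland and mining on ridges and urban,
  pasture and water in valleys. Roads are drawn first as one-cell Bresenham
  polylines linking urban nuclei (linear threats exercise cost distance
  differently from blobs). Mean patch size defaults to 1,200 cells
  (~1 km² at 30 m), giving the fragmented mosaic the prioritization stage
  needs.
* **Soil** — `n_soil_types` (4) codes by elevation band, median-smoothed;
  erodibility K is looked up per code.
* **Erosivity** — a smooth random field generated on 900-m blocks and
  block-replicated to the analysis resolution (mirroring a coarse rainfall
  product against a 30-m grid), spanning 5,000–12,000 MJ·mm/(ha·h·yr) by
  default — a realistic range for a humid subtropical region.
* **Protected areas** — rotated-ellipse polygons, labels 1 (strict) and 2
  (sustainable use), strict drawn last where they overlap.

Parameter tables (threat `d_max`/weights, carbon pools, USLE C/P,
filtration, soil K) are synthetic literature-scale defaults for a tropical
mining-province mosaic; they are configuration, not estimates, and any real
application should supply its own CSVs. What passing tests on these
landscapes shows is that the *algorithms* behave correctly under realistic
structure; they say nothing about the predictive accuracy of any particular
parameterization on real terrain, and the generator omits real-data
features such as classification error, mixed pixels, registration offsets
between layers, and anisotropic geology.

## Terrain

* **Slope** — Horn 3×3 finite differences, degrees; borders use
  edge-replicated neighborhoods.
* **Slope-corrected distance** — `d_a = cell / cos(θ)`, clamped at θ = 89°
  to keep the cosine away from zero (a numerical cap, not a physical
  claim).
* **Maximum curvature** — per cell, a bivariate quadratic is least-squares
  fitted to all cells within a 500-m radius (the window realizes the
  "radius of influence"; fitting, not smoothing). The reported value is
  the principal curvature of the negated Hessian with the larger
  magnitude, signed so convex-up crests are positive. Units 1/m, but only
  the ranking matters downstream.
* **Barriers** — exactly `ceil(0.20 × n_valid)` top-curvature cells are
  recoded to 300; ties at the quantile are admitted in row-major order so
  the count is reproducible. Summing a recoded curvature with `d_a`
  sidesteps the unit mismatch a raw curvature + distance sum would have:
  the barrier value is an opaque prohibitive cost, which is what the
  operational procedure calls for.
* **Cost distance** — least accumulated cost over 8-connected moves, a move
  costing the mean of the two endpoint cell costs (×√2 diagonally),
  computed by Dijkstra on the sparse grid graph. Source cells are 0;
  unreachable valid cells are +inf (their impact is 0 downstream).
* **Hydrology** — pits are filled by morphological reconstruction (erosion)
  anchored at the grid border and at cells adjacent to nodata; flats are
  resolved by a breadth-first sweep from their spill cells; D8 directions,
  upstream-cell counts, and sub-watershed labels follow. Watersheds start
  as terminal-cell basins and are merged greedily — smallest first, into
  the adjacent basin with the longest shared boundary, ties by label id —
  until every labeled basin reaches `min_area_km2` (default 36). A grid
  smaller than the minimum is one watershed.

## Habitat quality

Decay constant 2.99 = −ln 0.05: impact falls to 5% at `d_max`. Each threat
class uses the cost distance to its *nearest* source cell, giving one
impact surface per class; the per-source-pixel summation of the original
formulation is not recoverable from a nearest-source cost-distance product,
and the nearest-source form is what a GIS cost-distance run yields. All
habitat classes are equally sensitive to all threats. The accessibility
factor β (default 0.5) applies multiplicatively and only inside strictly
protected areas; sustainable-use areas and any explicitly excluded reserve
labels get β = 1. Quality uses the half-saturation constant
`k_half = 0.5`; non-habitat cells are 0 by definition.

## Carbon

Edge classification uses a Euclidean distance transform on cell centers
(not a cell-count buffer), recoding forest within 100 m of valid non-forest
to the forest-edge class; it is idempotent because edge cells still count
as forest for the transform. The below-ground allometry defaults to
`BGB = exp(−1.0587 + 0.8836 ln AGB)` (root:shoot ≈ 0.20 at 100 Mg/ha); the
positive-intercept variant found in parts of the allometry literature is
reachable through `coeff_a` but implies BGB > AGB and is not the default.
The 50% carbon fraction applies to AGB, BGB and dead organic matter; SOC
table values are treated as carbon already, since soil surveys report
carbon rather than biomass. Edge effects alter only forest biomass pools —
the mechanism is tree mortality — unless the table says otherwise.

## Sediment

LS follows Desmet–Govers: the length factor uses the upstream contributing
area at the cell inlet (D8 accumulation × cell area) with the exponent
`m = β/(1+β)`, `β = (sinθ/0.0896)/(3·sin^0.8 θ + 0.56)`, reference length
22.13 m; the slope factor is McCool's two-piece form (break at 9% slope).
A flat cell with no upstream area reduces to L = 1, S = 0.03. Routing
processes cells upstream-first: each cell generates `A = R·K·LS·C·P`,
intercepts `filt_eff × incoming` (credited to its retention), and passes
the rest downstream; terminal cells export. Retention is avoided erosion
`R·K·LS·(1−C·P)` plus interception. The scheme conserves mass to machine
precision (asserted in tests at 1e-6 relative), and a coarser erosivity
raster is nearest-neighbor resampled by block replication in the
generator.

## Sensitivity

Pixels are sampled uniformly without replacement from cells valid in every
participating raster. Response and predictors are z-scored with the sample
(n−1) standard deviation; SRCs are OLS coefficients on the standardized
scale. Uncertainty comes from a nonparametric bootstrap (default 1,000
resamples) that re-standardizes within each resample, so the percentile CI
reflects the whole estimator; analytic OLS standard errors are available
via `method="analytic"`. Constant predictors are dropped with a warning;
exact collinearity raises. SRCs can leave [−1, 1] when predictors are
correlated — values are reported unclipped with a warning, since clipping
would hide the collinearity.

## Prioritization

Rescaling divides by the map maximum (×100); sediment retention is
log10(1+x)-transformed first so zero-retention cells stay defined.
Correlations use all jointly valid cells. The top-quantile mask takes
exactly `ceil(0.20 × n_valid)` cells with row-major tie-breaking; the
priority mask requires membership in ≥2 of the three service masks. The
aggregation index counts, per priority cell, the other priority cells
whose centers lie within 250 m (self excluded, configurable); it is
evaluated by convolution with a disk kernel and is symmetric by
construction. Areas are reported in km² from the cell size.

## Problem sizes and determinism

The test suite runs the full pipeline at 250×250 cells (30 m), the
watershed delineation check at 1200×1200, the SRC recovery study at
n = 10,000 × 50 replicates, and the oracle equivalences on 6×6 to 20×20
grids — sizes chosen so the whole suite completes in well under a minute
while still containing several watersheds, hundreds of patches and
thousands of boundary cells. Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); identical seeds give bit-identical
rasters and tables.

## Limitations

* Single-direction (D8) routing only; no multiple-flow-direction option.
* No CRS or reprojection; inputs must already be aligned.
* The nearest-source threat semantics understate degradation where many
  source pixels of one class surround a cell at similar distances.
* Sediment routing has no channel network or deposition re-entrainment;
  filtration is a per-class constant, not a hydraulic model.
* The bundling and priority thresholds (20%, ≥2 services, 250 m) are
  policy choices exposed as parameters, not estimated quantities.
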