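# Methods

## Scope and model

`lurmap` evaluates fixed, published land-use-regression (LUR) models on a
raster grid; it does not fit models. Each pollutant surface is

    C(s) = β0 + Σj βj · Xj(s)

per cell `s`, with predictors drawn from three families: circular-buffer
sums of per-cell quantities, inverse distances to the (major) road
network, and IDW-interpolated regional background estimates. The six
built-in models (NO2, NO2 background, NOx, PM2.5, PM2.5 absorbance, PM10)
reproduce the published coefficient tables exactly; models are data
(JSON), so the same machinery applies to user-supplied models over the
same predictor vocabulary. Re-estimating coefficients from monitoring
data is deliberately out of scope.

## Grid conventions

Grids are square-celled on a projected metric CRS (the Dutch national maps
use EPSG:28992 at 5 m). Row 0 is the northern edge. Cells are half-open:
a cell owns `[edge, edge + cell_size)` going east and south, which makes
point-in-cell queries unambiguous; a point on an east/south cell edge
belongs to the neighbour. All computation is float64 — 5000 m buffers at
5 m cells accumulate ~3×10⁶ terms per cell and float32 accumulation
drifts — though files may be written float32 on request. NODATA is carried
as a boolean mask internally (so no sentinel can contaminate arithmetic)
and materialised as −9999 in files, with the GDAL_NODATA tag in GeoTIFF.
NODATA propagates through arithmetic and model evaluation; aggregations
exclude it.

## Rasterization

*Roads.* Each polyline edge is clipped against the grid by parametric
(Liang–Barsky) traversal: the edge is cut at every grid line, each piece
is assigned to the cell containing its midpoint, and piece lengths are
parameter increments times edge length. Per-cell lengths therefore sum to
the clipped network total to machine precision. Traffic load multiplies
clipped length by the segment's intensity (vehicles·day⁻¹), so the load
raster is exactly the intensity-weighted sum of length rasters. A missing
intensity attribute is an error naming the segment, never an implicit
zero: traffic-load terms carry large weights in the models and zero-filling
would bias them low.

*Polygons.* Land-use classes (reclassified to IND/HAR/RES) and population
zones use cell-centre membership, the `gdal_rasterize` convention: a 5 m
cell is fully in a class (25 m²) or not at all. Fractional-coverage
rasterization would change buffer sums only in a one-cell band along
polygon borders. Population counts are spread uniformly over a zone's
covered cells (no dasymetric refinement); a zone too small to cover any
centre falls back to its representative cell so totals are conserved.

## Circular buffers

Kernel membership is by cell-centre distance with a closed comparison
(≤ radius), decided in exact rational arithmetic so boundary ties are
deterministic — e.g. the (3,4,5) integer triangle lies exactly on the
25 m circle at 5 m cells and is included, giving the classic 81-cell
disk. The annulus (e.g. HTL_25−500) is computed with a ring kernel
directly, not as a difference of two disk sums, so its value is exactly
the sum over ring cells. Outside the grid, contributions are zero
(zero padding): buffer sums near the domain border are underestimates,
the correct behaviour when no data exist beyond the border.

Two implementations produce bit-identical results per kernel:

- kernels of ≤ 10 000 cells: shifted-array accumulation over offsets in
  sorted (Δrow, Δcol) order, which per cell reproduces a sequential
  brute-force loop bit for bit (the engine's testable contract);
- larger kernels: per-kernel-row sliding-window sums built from per-row
  prefix sums, accumulated over kernel rows in fixed order. Each output
  row depends only on whole input rows, so processing the grid in
  horizontal bands (`tile_rows`) reproduces the untiled result bitwise —
  the desk-scale equivalent of tiling national grids across machines.

The path is selected from kernel size alone, so a given radius always
takes the same path regardless of tiling or grid shape.

## Distances and inverse distance

Distances are exact Euclidean point-to-segment minima from each cell
centre to the vector geometry (not to rasterized roads), vectorised over
cell chunks. IDC/IDM are 1/max(d, d_min). The clamp exists because a grid
evaluated everywhere includes on-road cells with d = 0, where a raw
inverse distance diverges; address-point evaluations never faced this.
d_min defaults to half a cell (2.5 m) and is configurable; on-road cells
take 1/d_min (0.4 m⁻¹ at defaults).

## IDW backgrounds

BEO/BEX/BEP/BEA are inverse-distance-weighted means of regional station
values with search radius 100 km (the published constant) and exponent
p = 2. The exponent of the original maps is unpublished; 2 is the
conventional default of the tool they used and is exposed as a parameter,
so surfaces with other exponents are one config line away. Cells within
cell_size/100 of a station take the station value exactly; cells with no
station in range are NODATA. IDW values are convex combinations, so the
surface is bounded by the station minimum and maximum. PM10 has no
background term by design (it did not improve that model); requesting one
is an error.

## Model evaluation

Per-cell map algebra: intercept plus coefficient-weighted predictor
rasters on a common grid; mismatched grids or missing terms are errors
naming the term. Negative predicted concentrations are reported (counted
in the evaluation summary) but not clipped by default — silent truncation
would hide application of a model outside its domain; `clip_zero=True` is
available. Point extraction returns the containing cell's value with no
sub-cell interpolation (the surface is cell-constant by construction);
out-of-extent points are flagged, not dropped. PMcoarse is the cellwise
difference PM10 − PM2.5 and may be negative where the surfaces cross.

Naming: the literature uses both "MTL" and "TML" for major-road traffic
load; TML is canonical here and MTL is accepted as an input alias.
Buffered POP terms are treated as inhabitant counts within the buffer
(per-cell inhabitants summed), which is the consistent reading of a
density-sourced raster aggregated over buffer areas.

## Validation statistics

r² is the squared Pearson correlation of observed and modelled values —
the usual LUR-validation convention, symmetric in the two vectors; it
differs from regression R² except at a perfect fit. RMSE and bias use the
observed-minus-modelled convention. The bias test is a two-sided
one-sample t-test of the differences against zero; degenerate cases are
fixed conventions (all-zero differences → t=0, p=1; constant nonzero
differences → p=0, flagged by an infinite t). Station screening excludes
stations with strictly more than a given missing fraction (default 20%)
and averages the survivors over the supplied period.

## Synthetic scene

The generator emulates the *structure* of the real inputs, not their
statistics: a ring road plus crossing arterials ("major", 10–40k
vehicles/day), a minor street grid (0.5–5k), 10% heavy traffic,
axis-aligned land-use blocks, population spread over residential blocks,
regional background stations carrying a smooth linear-trend field with 3%
scatter, and uniformly placed validation sites. Defaults: 2 km × 2 km at
5 m (400×400 cells), 50 000 inhabitants, 10 background stations (a
PM-sized regional network; pass 20 for an NOx-sized one), 200 validation
sites, 2 µg m⁻³ observation noise. Axis-aligned lattice geometry is a
deliberate choice: rectangle areas and line lengths have closed forms and
serve as analytic test oracles.

Everything is a pure function of the seed; fixture files are
byte-reproducible. Synthetic observations are the model's own surface
plus seeded Gaussian noise, which gives the pipeline a parameter-free
identity check (noise 0 → r²=1, RMSE=0, bias=0) and a calibration check
(RMSE → σ, bias → 0 at rate σ/√n). What passing these tests does *not*
show: performance on real geodata with curved roads, fractional land-use
coverage, spatially structured model error, or measurement error that is
non-Gaussian or correlated with traffic — validation numbers on real
scenes cannot be inferred from the synthetic ones.

## Numerical and design notes

- GeoTIFF I/O is built directly on the TIFF tag conventions
  (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL_NODATA) and
  round-trips float64 values and georeferencing bit-exactly; ESRI ASCII
  grid is supported for human-readable interchange and round-trips at
  printed precision (full `repr` precision in practice). PCRaster's
  binary format is not supported; GeoTIFF is the open equivalent.
- No reprojection: the CRS is an opaque label checked only for being
  projected/metric; inputs must already share the working CRS.
- GeoJSON is the single vector dialect; stations are CSV with
  `id,x,y,value[,site_type]`.
- Problem sizes in the test suite are chosen for a single-CPU desk run:
  oracle equivalence uses 50×50 grids at radii up to 125 m (where the
  brute-force loop is itself exact), the large-kernel path is checked at
  600 m against brute force at float tolerance, and end-to-end checks run
  the full 400×400 default scene, which completes in seconds.
- Known limitations: no road-width modelling (lane centrelines only), no
  kriging alternative to IDW, no temporal adjustment of station series,
  and border cells underestimate large-radius buffer sums by
  construction.
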