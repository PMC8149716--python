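# Methods

## The model

`foragescape` models the suitability of desert landscape patches for daily
foraging as a fuzzy multi-criteria overlay of three environmental surfaces
on a common projected ~30 m grid:

1. **Water accessibility (var1).** A surface-water occurrence raster (the
   percentage of satellite observations in which water was detected per
   cell) is thresholded at occurrence **> 5.0 %** (strict) into a binary
   detected-water mask. For every cell, the minimal walking time in hours
   to any water cell is computed over the DEM with Tobler's hiking function

   `speed(s) = 6 · exp(−3.5 · |s + 0.05|)  km/h`,

   where `s` is the signed slope (rise/run) along the direction of travel —
   fastest on a gentle −5 % descent, slower both climbing and on steep
   descents. Travel is modelled *patch → water* (the forager leaves the
   patch to fetch water), so edge slopes are signed cell → water. The
   hours field is rescaled by a clamped linear membership anchored at
   0 h → 1 and 16 h → 0 (8 h → 0.5).

2. **Maximum vegetation greenness (var2).** The per-cell 95th percentile of
   an NDVI time stack (NDVI = (NIR − Red)/(NIR + Red)) summarizes the best
   observed vegetation state; it is rescaled with anchors 0.0 → 0 and
   0.3 → 1 (0.15 → 0.5), 0.3 being healthy arid-zone grass.

3. **Terrain ruggedness (var3).** The terrain ruggedness index (TRI) is the
   mean absolute elevation difference between a cell and its available 3×3
   neighbors; membership anchors are 0 → 1 and 17 → 0 (8.5 → 0.5). TRI
   < 3.5 reads as level ground, 3.5–17 as dunes and scree, > 17 as
   escarpments and uplands.

The suitability index is the equal-weight mean `S = (var1 + var2 + var3)/3`
(weights are configurable on the simplex but default equal; no weight
optimization or sensitivity analysis is attempted). Before any statistics,
open-water cells (raw occurrence > 5 %) and montane uplands (raw TRI > 17)
are masked with per-cell reasons — water is not a foraging patch and
uplands are treated as refugia outside the model. Pairwise Pearson
correlations of the three variables are reported as an independence
diagnostic; a constant variable makes the correlation undefined and is
flagged rather than silently zeroed.

The unmasked S population is classified at its Jenks natural breaks into
three classes. Boundary rule: a value exactly at a break belongs to the
lower class (low: S ≤ b1; moderate: b1 < S ≤ b2; high: S > b2). Zonal
statistics (pixel count, area km², mean/min/max/sd — population sd by
default) are tabulated per zone and class over unmasked cells only, cells
belonging wholly to the zone of their center.

## Numerical choices

- **Walking time** is an exact multi-source Dijkstra over the directed grid
  graph (all water cells enter the heap at zero cost; edges are reversed so
  one sweep yields patch → water costs). Connectivity is 8 by default
  (queen moves, diagonal length √2·cell); 16 (knight moves) reduces
  metrication error. Slope between adjacent cells is Δz over horizontal
  distance. Unreachable cells carry +inf (distinct from nodata) and map to
  membership 0. No accumulation cutoff is applied by default; `max_hours`
  exists as an optimization since everything beyond 16 h scores 0 anyway.
- **TRI** follows the mean-absolute-difference wording; the
  root-sum-of-squares convention common elsewhere is available as
  `method="rss"`. Edge cells use the neighbors they have; nodata neighbors
  are excluded; a cell with no valid neighbor is nodata. The mean-abs
  default is the form consistent with the published 8.5 → 0.5 worked
  example.
- **var3 anchors** are (0 → 1, 17 → 0). A 1–17 ramp would give
  8.5 → 0.53125, contradicting the printed 8.5 → 0.5; the worked values
  outrank the prose range.
- **Percentile composite** interpolates linearly between order statistics
  and uses valid observations only (no gap-filling); a cell with zero valid
  observations is nodata.
- **Jenks breaks** are computed by exact Fisher–Jenks dynamic programming.
  Because the optimal partition never splits tied values (interval SSD is
  concave in the number of tied items moved across a boundary), the DP runs
  over unique values with multiplicities; each layer is minimized by
  divide-and-conquer exploiting the quadrangle inequality of interval SSD,
  so the fit is exact in O(k·u·log u). Populations above `max_sample`
  (default 100 000) are reduced by a seeded uniform subsample; sample size,
  seed and goodness-of-variance fit (gvf = 1 − SSD_within/SSD_total) are
  recorded in the run manifest. Reported breaks are the maximum value of
  each lower class.
- **Grids** must be pre-aligned (identical shape and transform); the
  `snap_to` nearest-neighbor resampler is an explicit preprocessing step,
  never applied implicitly. Geographic (degree) grids are rejected since
  walking time needs metric distances. Nodata propagates: any stage's
  output is nodata where a required input is nodata. Tests compare floats
  at absolute tolerance 1e−6 or tighter; walking time is checked at 1e−9
  relative against an independent Dijkstra.
- GeoTIFF I/O is implemented directly over `tifffile`, writing the pixel
  scale, tiepoint, projected-CRS GeoKey and GDAL nodata tags; float
  payloads round-trip bit-faithfully at float32.

## The synthetic landscape

Real inputs for this model are continental satellite products; the package
ships a generator that emulates their structure at desk scale so every
stage is testable without a download. The DEM is a closed-form flat base
(100 m) plus sinusoidal dune ridges and cosine-bell upland blocks; default
amplitudes are sized so dune flanks land in the TRI 3.5–17 band and upland
flanks cross TRI 17 (the default 512×512 landscape: three uplands of
360–400 m over ~640–750 m radii, one dunefield of 25 m amplitude and 300 m
wavelength — flank slopes ~0.26, like steep desert linear dunes). Water
sites are drawn at or below median elevation: persistent waterholes get
occurrence in (20, 90] %, ephemeral ones in (0.5, 5] % — deliberately at or
below the 5.0 % cut so thresholding has an exactly known survivor count.
NDVI is `base (0.12) + seasonal sinusoid (±0.08) + proximity boost (0.25,
tapering to zero at 1.5 km from detected water) + N(0, 0.03) noise`,
clipped to [−1, 1]; water counts scale with grid area from 12 persistent +
30 ephemeral at 512×512. Zones are rectangular tiles.

Each product draws from its own named substream of the master seed, so
changing the NDVI stack length never moves the waterholes, and everything
is bit-reproducible under (config, seed).

What the generator does *not* emulate: radiometric and atmospheric
effects, cloud gaps, spatially correlated NDVI noise, realistic hydrology
or dune morphology, and irregular bioregion shapes. Passing tests therefore
demonstrate the correctness of the algorithms and their accounting, not the
ecological fidelity of any particular real-world map.

## Problem sizes

The default end-to-end configuration is a 512×512 grid (≈236 km²) with 24
NDVI timesteps; a full run takes on the order of ten seconds on one CPU.
Oracle suites run on small grids (≤ 10×10 walking-time graphs against an
explicit-edge Dijkstra; ≤ 15-value multisets against exhaustive partition
enumeration for the break fit), where brute force is exact and fast.

## Known limitations

- The walking-time graph discretizes direction to 8 (or 16) neighbors;
  path times carry lattice metrication error relative to continuous space,
  and the original GIS tool's internal discretization is not documented, so
  real-data outputs may differ slightly in the last digits.
- Equal weighting of the three variables is an assumption inherited from
  the source analysis, not an estimate.
- Class breaks are data-dependent: they are refitted per landscape and are
  not transferable constants.
- Vector zones must be rasterized upstream; only raster zones are
  supported.
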