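# foragescape

Raster modelling of **foraging-habitat suitability** for arid landscapes,
built for spatial ecologists and archaeologists who want a tested,
reproducible version of the classic satellite-derived workflow: how
favorable is each ~30 m patch of desert for day-to-day foraging, given
where surface water is, how green the vegetation gets, and how rugged the
terrain is?

## The model

Three environmental surfaces on a common projected grid are each rescaled
to [0, 1] by a clamped two-anchor linear membership function and averaged:

- **var1 — water accessibility.** Water-occurrence % is thresholded at
  > 5.0 % into detected water; per-cell minimal walking hours to water are
  computed over the DEM with Tobler's hiking function
  `v(s) = 6·e^(−3.5·|s+0.05|)` km/h (anisotropic in slope sign, exact
  multi-source Dijkstra); membership anchors 0 h → 1, 16 h → 0 (8 h → 0.5).
- **var2 — maximum greenness.** 95th-percentile composite of an NDVI time
  stack; anchors 0.0 → 0, 0.3 → 1 (0.15 → 0.5).
- **var3 — terrain ruggedness.** TRI = mean |Δelevation| over the 3×3
  neighborhood; anchors 0 → 1, 17 → 0 (8.5 → 0.5).

```
S = (var1 + var2 + var3) / 3,   S ∈ [0, 1]
```

Open water (occurrence > 5 %) and montane uplands (TRI > 17) are masked,
the unmasked S population is classified at its **Jenks natural breaks**
into low / moderate / high foraging habitat, and zonal statistics (pixel
counts, km², mean/min/max/sd of e.g. the NDVI composite) are tabulated per
zone and class. A synthetic landscape generator (DEM with dunes and
uplands, persistent and ephemeral waterholes, seasonal greener-near-water
NDVI) exercises the whole pipeline without any satellite download.

## Worked example

```python
import foragescape as fs

cfg = fs.LandscapeConfig.default(shape=(128, 128), seed=42)
res = fs.ForagingHabitatModel.from_synthetic(cfg).fit(seed=42)
print(res.summary())
```

```
      Foraging Habitat Suitability Model
========================================================
grid:            128 x 128 @ 30 m
water cells:     1 (occurrence > 5 %)
masked:          1 open water, 297 montane upland, 0 nodata
population:      16086 cells
--------------------------------------------------------
S mean / sd:     0.845 / 0.056   skewness: 0.240
Jenks breaks:    0.818, 0.883   (gvf = 0.8417, n fitted = 16086)
correlations:    var1:var2 +0.6049  var1:var3 +0.3229  var2:var3 +0.0773
--------------------------------------------------------
class     area_km2      percent
low            5.27       36.4 %
moderate       5.36       37.0 %
high           3.85       26.6 %
========================================================
```

Reading it: one waterhole survived the 5 % occurrence threshold; 297 cells
of steep upland flanks were masked out of the population of 16 086. The
fitted natural breaks 0.818 / 0.883 split the S surface so that 26.6 % of
the unmasked area (3.85 km²) is high-ranked habitat — the cells that are
simultaneously near water, green at their seasonal best, and easy to walk.
The correlation row is the variable-independence diagnostic (here var1 and
var2 correlate because the synthetic NDVI is greener near water by
construction). `res.class_areas()` and `res.zonal_ndvi()` return the full
per-zone tables as DataFrames; `foragescape.plots.plot_results(res, dir)`
writes the class map, S histogram, class-share bars and NDVI boxplots.

The same analysis runs from the shell:

```bash
foragescape run --synthetic --out-dir run1 --seed 42   # full pipeline + manifest
foragescape synth --shape 256 256 --seed 1 --out-dir inputs/
foragescape var1 --occurrence inputs/water_occurrence.tif --dem inputs/dem.tif --out var1.tif
```

Every run writes a `manifest.yaml` (breaks, gvf, correlation matrix, mask
counts, class areas, seeds, timings) from which it can be re-executed
bit-identically.

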