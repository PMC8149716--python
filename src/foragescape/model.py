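"""Model/Results facade over the suitability pipeline.

:class:`ForagingHabitatModel` is constructed from the raw input surfaces
(water occurrence, NDVI time stack, DEM, optional zones); ``fit()`` derives
the three fuzzy variables, combines them into S, masks open water and
uplands, fits the Jenks natural breaks, classifies the landscape and
returns a :class:`ForagingHabitatResults` carrying every estimate and
diagnostic: the breaks and their goodness-of-variance fit, the variable
correlation matrix, the S distribution moments, class areas and zonal
tables, plus the intermediate rasters.  ``summary()`` prints the usual
one-screen fit report.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import variables as dv
from . import walktime as wt
from .jenks import ClassBreaks, jenks_breaks
from .raster import GridRaster, ZoneRaster, assert_aligned
from .suitability import (
    CLASS_NAMES,
    SuitabilityClassField,
    SuitabilityField,
    apply_masks,
    classify,
    combine,
    correlation_matrix,
    distribution_summary,
)
from .zonal import class_area_percent, zonal_table

__all__ = ["ForagingHabitatModel", "ForagingHabitatResults"]


class ForagingHabitatModel:
    """Foraging-habitat suitability model over aligned raster inputs.

    Parameters
    ----------
    occurrence
        Surface-water occurrence raster (% of observations with water).
    ndvi_stack
        Time stack of NDVI rasters on the same grid.
    dem
        Digital surface model in meters.
    zones
        Optional zone raster (bioregion analogue) for the zonal tables.
    water_cutoff_pct, ndvi_percentile, connectivity, tri_method,
    upland_cutoff_tri, weights, k
        Tunable stage parameters; defaults are the reference analysis
        constants (5.0 % water cut, 95th-percentile greenness, 8-connected
        walking graph, mean-|dz| TRI, TRI 17 upland cut, equal weights,
        three classes).
    """

    def __init__(
        self,
        occurrence: GridRaster,
        ndvi_stack: list[GridRaster],
        dem: GridRaster,
        zones: ZoneRaster | None = None,
        *,
        water_cutoff_pct: float = 5.0,
        ndvi_percentile: float = 95.0,
        connectivity: int = 8,
        tri_method: str = "mean_abs",
        upland_cutoff_tri: float = 17.0,
        weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
        k: int = 3,
        jenks_max_sample: int = 100_000,
    ) -> None:
        rasters = [occurrence, dem] + list(ndvi_stack)
        names = ["occurrence", "dem"] + [f"ndvi[{i}]" for i in range(len(ndvi_stack))]
        assert_aligned(rasters, names)
        if zones is not None and zones.shape != dem.shape:
            raise ValueError("zone raster misaligned with inputs")
        self.occurrence = occurrence
        self.ndvi_stack = list(ndvi_stack)
        self.dem = dem
        self.zones = zones
        self.water_cutoff_pct = float(water_cutoff_pct)
        self.ndvi_percentile = float(ndvi_percentile)
        self.connectivity = int(connectivity)
        self.tri_method = tri_method
        self.upland_cutoff_tri = float(upland_cutoff_tri)
        self.weights = weights
        self.k = int(k)
        self.jenks_max_sample = int(jenks_max_sample)

    @classmethod
    def from_synthetic(cls, cfg, zones: bool = True, **kw) -> "ForagingHabitatModel":
        """Build the model from a :class:`~foragescape.synth.LandscapeConfig`."""
        from . import synth

        dem = synth.generate_dem(cfg)
        occ = synth.generate_water_occurrence(cfg, dem)
        stack = synth.generate_ndvi_stack(cfg, dem, occ)
        z = synth.generate_zones(cfg) if zones else None
        return cls(occ, stack, dem, z, **kw)

    def fit(self, seed: int = 0) -> "ForagingHabitatResults":
        """Run the full derivation and return the fitted results.

        ``seed`` only matters when the unmasked population exceeds
        ``jenks_max_sample`` and the break fit subsamples.
        """
        mask = wt.threshold_water(self.occurrence, self.water_cutoff_pct)
        hours = wt.walking_time(self.dem, mask, self.connectivity)
        var1 = wt.water_accessibility(hours)
        comp = dv.percentile_composite(self.ndvi_stack, self.ndvi_percentile)
        var2 = dv.greenness_membership(comp)
        tri_field = dv.tri(self.dem, method=self.tri_method)
        var3 = dv.ruggedness_membership(tri_field)
        # degenerate landscapes (a constant variable) have no defined
        # correlation; the fit still completes but carries the flag
        corr_warning = None
        try:
            corr = correlation_matrix(var1, var2, var3)
        except ValueError as exc:
            corr = np.full((3, 3), np.nan)
            np.fill_diagonal(corr, 1.0)
            corr_warning = str(exc)
        S = combine(var1, var2, var3, self.weights)
        S = apply_masks(S, self.occurrence, tri_field,
                        self.water_cutoff_pct, self.upland_cutoff_tri)
        breaks = jenks_breaks(
            S.unmasked_values, k=self.k, max_sample=self.jenks_max_sample, seed=seed
        )
        classes = classify(S, breaks)
        return ForagingHabitatResults(
            model=self,
            water_mask=mask,
            walk_hours=hours,
            var1=var1,
            var2=var2,
            var3=var3,
            ndvi_composite=comp,
            tri_field=tri_field,
            corr=corr,
            suitability=S,
            breaks=breaks,
            classes=classes,
            seed=int(seed),
            corr_warning=corr_warning,
        )


@dataclasses.dataclass
class ForagingHabitatResults:
    """Fitted suitability surface, classification and diagnostics."""

    model: ForagingHabitatModel
    water_mask: wt.BinaryWaterMask
    walk_hours: wt.WalkTimeField
    var1: GridRaster
    var2: GridRaster
    var3: GridRaster
    ndvi_composite: dv.NDVIComposite
    tri_field: dv.TRIField
    corr: np.ndarray
    suitability: SuitabilityField
    breaks: ClassBreaks
    classes: SuitabilityClassField
    seed: int
    corr_warning: str | None = None

    @property
    def S(self) -> np.ndarray:
        return self.suitability.S

    @property
    def gvf(self) -> float:
        return self.breaks.gvf

    def distribution(self) -> dict:
        """Moments (mean, sd, skewness, n) of the unmasked S population."""
        return distribution_summary(self.suitability)

    def class_areas(self) -> pd.DataFrame:
        """Per-zone and whole-area class areas and percentages."""
        zones = self.model.zones or self._whole_area_zone()
        return class_area_percent(self.classes, zones, self.suitability)

    def zonal_ndvi(self) -> pd.DataFrame:
        """Zonal table of the NDVI composite by zone and suitability class."""
        zones = self.model.zones or self._whole_area_zone()
        return zonal_table(self.ndvi_composite.raster, zones, self.classes, self.suitability)

    def _whole_area_zone(self) -> ZoneRaster:
        ids = np.ones(self.suitability.raster.shape, dtype=np.int32)
        return ZoneRaster(ids, self.suitability.raster.transform, {1: "study area"})

    def mask_counts(self) -> dict[str, int]:
        reason = self.suitability.masked_reason
        return {
            "unmasked": int(self.suitability.unmasked.sum()),
            "open_water": int((reason == 1).sum()),
            "montane_upland": int((reason == 2).sum()),
            "nodata": int((reason == 3).sum()),
        }

    def summary(self) -> str:
        """One-screen fit report in the style of a regression summary."""
        dist = self.distribution()
        areas = self.class_areas()
        whole = areas[areas.zone_id == 0]
        masks = self.mask_counts()
        b1, b2 = self.breaks.breaks
        lines = [
            "      Foraging Habitat Suitability Model",
            "=" * 56,
            f"grid:            {self.suitability.raster.shape[0]} x {self.suitability.raster.shape[1]}"
            f" @ {self.suitability.raster.cell_size_m:g} m",
            f"water cells:     {self.water_mask.n_water}"
            f" (occurrence > {self.model.water_cutoff_pct:g} %)",
            f"masked:          {masks['open_water']} open water, "
            f"{masks['montane_upland']} montane upland, {masks['nodata']} nodata",
            f"population:      {dist['n']} cells",
            "-" * 56,
            f"S mean / sd:     {dist['mean']:.3f} / {dist['sd']:.3f}"
            f"   skewness: {dist['skewness']:.3f}",
            f"Jenks breaks:    {b1:.3f}, {b2:.3f}   (gvf = {self.gvf:.4f},"
            f" n fitted = {self.breaks.sample_size})",
            "correlations:    "
            f"var1:var2 {self.corr[0, 1]:+.4f}  var1:var3 {self.corr[0, 2]:+.4f}"
            f"  var2:var3 {self.corr[1, 2]:+.4f}",
            "-" * 56,
            "class     area_km2      percent",
        ]
        for _, row in whole.iterrows():
            lines.append(f"{row['class']:<9} {row.area_km2:>9.2f}     {row.percent:>6.1f} %")
        lines.append("=" * 56)
        return "\n".join(lines)
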