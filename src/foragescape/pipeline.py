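"""One-command orchestration: synth -> var1/var2/var3 -> model -> zonal -> manifest.

A run is described by a :class:`RunConfig` (YAML-serializable), executes the
stages in dependency order on a synthetic or on-disk landscape, writes every
output raster and table under an output directory, and records a manifest
(config echo, seeds, breaks, gvf, correlation matrix, mask counts, class
areas, per-stage timings) from which the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from .model import ForagingHabitatModel, ForagingHabitatResults
from .raster import (
    GridRaster,
    read_raster,
    read_zone_raster,
    write_raster,
    write_zone_raster,
)
from .synth import (
    LandscapeConfig,
    generate_dem,
    generate_ndvi_stack,
    generate_water_occurrence,
    generate_zones,
)

__all__ = ["RunConfig", "run_pipeline", "write_synthetic_inputs"]

log = logging.getLogger("foragescape")


@dataclasses.dataclass
class RunConfig:
    """Full description of a pipeline run; defaults are the model constants."""

    out_dir: str = "foragescape_run"
    synthetic: bool = True
    landscape: LandscapeConfig = dataclasses.field(default_factory=LandscapeConfig.default)
    # on-disk inputs, used when synthetic = False
    occurrence_path: str | None = None
    dem_path: str | None = None
    ndvi_glob: str | None = None
    zones_path: str | None = None
    # stage parameters (reference-analysis constants)
    water_cutoff_pct: float = 5.0
    ndvi_percentile: float = 95.0
    connectivity: int = 8
    tri_method: str = "mean_abs"
    upland_cutoff_tri: float = 17.0
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    jenks_k: int = 3
    jenks_max_sample: int = 100_000
    seed: int = 0
    write_rasters: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"] = list(d["weights"])
        d["landscape"]["shape"] = list(self.landscape.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        land = d.pop("landscape", None)
        if land is not None:
            land = dict(land)
            land["shape"] = tuple(land["shape"])
            land["upland_blocks"] = [
                (tuple(c), r, h) for c, r, h in land.get("upland_blocks", [])
            ]
            land["dune_ridges"] = [tuple(t) for t in land.get("dune_ridges", [])]
            d["landscape"] = LandscapeConfig(**land)
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_synthetic_inputs(cfg: LandscapeConfig, out_dir: str | Path) -> dict[str, str]:
    """Generate and write dem/water/ndvi/zones GeoTIFFs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dem = generate_dem(cfg)
    occ = generate_water_occurrence(cfg, dem)
    stack = generate_ndvi_stack(cfg, dem, occ)
    zones = generate_zones(cfg)
    write_raster(dem, out / "dem.tif")
    write_raster(occ, out / "water_occurrence.tif")
    for i, r in enumerate(stack):
        write_raster(r, out / f"ndvi_{i:03d}.tif")
    write_zone_raster(zones, out / "zones.tif")
    manifest = {
        "config": {**dataclasses.asdict(cfg), "shape": list(cfg.shape)},
        "seed": cfg.seed,
        "files": ["dem.tif", "water_occurrence.tif", "zones.tif"]
        + [f"ndvi_{i:03d}.tif" for i in range(len(stack))],
    }
    with open(out / "synth_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {k: str(out / v) for k, v in
            {"dem": "dem.tif", "occurrence": "water_occurrence.tif", "zones": "zones.tif"}.items()}


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        dem = generate_dem(cfg.landscape)
        occ = generate_water_occurrence(cfg.landscape, dem)
        stack = generate_ndvi_stack(cfg.landscape, dem, occ)
        zones = generate_zones(cfg.landscape)
        return occ, stack, dem, zones
    if not (cfg.occurrence_path and cfg.dem_path and cfg.ndvi_glob):
        raise ValueError("non-synthetic run needs occurrence_path, dem_path and ndvi_glob")
    occ = read_raster(cfg.occurrence_path, "water-occurrence %")
    dem = read_raster(cfg.dem_path, "elevation m")
    paths = sorted(Path().glob(cfg.ndvi_glob)) or sorted(
        Path(cfg.ndvi_glob).parent.glob(Path(cfg.ndvi_glob).name)
    )
    if not paths:
        raise FileNotFoundError(f"no NDVI rasters match {cfg.ndvi_glob}")
    stack = [read_raster(p, "NDVI") for p in paths]
    zones = read_zone_raster(cfg.zones_path) if cfg.zones_path else None
    return occ, stack, dem, zones


def run_pipeline(cfg: RunConfig) -> ForagingHabitatResults:
    """Execute the full analysis; write rasters, tables and the run manifest.

    Any stage failure aborts with the stage named; the manifest is only
    written once every stage has completed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate which stage died
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %-10s %.2fs", name, timings[name])
        return result

    occ, stack, dem, zones = stage("inputs", lambda: _load_inputs(cfg))
    model = ForagingHabitatModel(
        occ, stack, dem, zones,
        water_cutoff_pct=cfg.water_cutoff_pct,
        ndvi_percentile=cfg.ndvi_percentile,
        connectivity=cfg.connectivity,
        tri_method=cfg.tri_method,
        upland_cutoff_tri=cfg.upland_cutoff_tri,
        weights=cfg.weights,
        k=cfg.jenks_k,
        jenks_max_sample=cfg.jenks_max_sample,
    )
    res = stage("fit", lambda: model.fit(seed=cfg.seed))
    areas = stage("class_areas", res.class_areas)
    ndvi_tab = stage("zonal_ndvi", res.zonal_ndvi)
    dist = res.distribution()

    if cfg.write_rasters:
        def dump():
            write_raster(res.var1, out / "var1.tif")
            write_raster(res.var2, out / "var2.tif")
            write_raster(res.var3, out / "var3.tif")
            hours = np.where(np.isinf(res.walk_hours.hours), np.nan, res.walk_hours.hours)
            write_raster(
                GridRaster(hours, dem.transform, band_meaning="walking hours to water"),
                out / "walk_hours.tif",
            )
            write_raster(res.ndvi_composite.raster, out / "ndvi95.tif")
            write_raster(res.tri_field.raster, out / "tri.tif")
            write_raster(res.suitability.raster, out / "S.tif")
            write_raster(
                GridRaster(
                    np.where(res.classes.classes == 0, np.nan, res.classes.classes),
                    dem.transform, nodata=255.0, band_meaning="suitability class",
                ),
                out / "classes.tif", dtype="uint8",
            )
        stage("write_rasters", dump)

    areas.to_csv(out / "class_areas.csv", index=False)
    ndvi_tab.to_csv(out / "zonal_ndvi.csv", index=False)

    whole = areas[areas.zone_id == 0]
    manifest = {
        "config": cfg.to_dict(),
        "breaks": [round(b, 6) for b in res.breaks.breaks],
        "gvf": round(res.gvf, 6),
        "jenks_sample_size": res.breaks.sample_size,
        "correlation_matrix": [[round(float(v), 6) for v in row] for row in res.corr],
        "distribution": {k: (round(v, 6) if isinstance(v, float) else v) for k, v in dist.items()},
        "mask_counts": res.mask_counts(),
        "class_percent": {
            str(row["class"]): round(float(row.percent), 3) for _, row in whole.iterrows()
        },
        "n_water_cells": res.water_mask.n_water,
        "n_unreachable": res.walk_hours.n_unreachable,
        "timings_s": timings,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(res.summary() + "\n")
    return res
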