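"""Synthetic desert-landscape generator for exercising the full pipeline.

Stands in for the three satellite products the suitability model consumes:
a digital surface model (flat base + sinusoidal dune ridges + smooth upland
blocks), a surface-water occurrence raster (persistent waterholes well above
the 5 % detection cut, ephemeral ones at or below it), and a seasonal NDVI
time stack that is greener near persistent water.  A rectangular zone raster
plays the role of bioregion boundaries.

Everything is deterministic under (config, seed): each product draws from
its own named substream of the master seed, so e.g. adding NDVI timesteps
never moves the waterholes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .raster import GridRaster, GridTransform, ZoneRaster

__all__ = [
    "LandscapeConfig",
    "generate_dem",
    "generate_water_occurrence",
    "generate_ndvi_stack",
    "generate_zones",
]

# named substreams so products are independently reproducible
_STREAM_WATER = 2
_STREAM_NDVI = 3

#: default occurrence ranges (%): persistent clearly above, ephemeral at or
#: below the 5.0 % detection threshold, so thresholding has a known
#: survivor count by construction.
_PERSISTENT_OCC = (20.0, 90.0)
_EPHEMERAL_OCC = (0.5, 5.0)


@dataclasses.dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Upland blocks are ``((row, col), radius_cells, height_m)`` cosine bells
    whose flanks are steep enough to push TRI past the 17 m upland break;
    dune ridges are ``(orientation_deg, wavelength_m, amplitude_m)``
    sinusoids sized to land in the 3.5-17 m dune/scree TRI band.
    """

    shape: tuple[int, int] = (512, 512)
    cell_size_m: float = 30.0
    seed: int = 0
    base_elevation_m: float = 100.0
    upland_blocks: list = dataclasses.field(default_factory=list)
    dune_ridges: list = dataclasses.field(default_factory=list)
    n_persistent_waters: int = 12
    n_ephemeral_waters: int = 30
    ndvi_timesteps: int = 24
    ndvi_base: float = 0.12
    ndvi_seasonal_amplitude: float = 0.08
    ndvi_water_boost: float = 0.25
    ndvi_boost_radius_m: float = 1500.0
    noise_sd: float = 0.03
    n_zones: int = 4

    def __post_init__(self) -> None:
        nrow, ncol = self.shape
        if nrow <= 0 or ncol <= 0:
            raise ValueError("shape must be positive")
        for name in ("n_persistent_waters", "n_ephemeral_waters", "ndvi_timesteps", "n_zones"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0 or self.ndvi_water_boost < 0:
            raise ValueError("noise_sd and ndvi_water_boost must be >= 0")

    @classmethod
    def default(cls, shape: tuple[int, int] = (512, 512), seed: int = 0, **kw) -> "LandscapeConfig":
        """The standard test landscape: three uplands, one dunefield, waters.

        Water-point counts scale with grid area (12 persistent + 30
        ephemeral on the 512x512 reference) so small grids keep realistic
        water density instead of drowning in greenness halos.
        """
        nrow, ncol = shape
        area_scale = (nrow * ncol) / (512 * 512)
        kw.setdefault("n_persistent_waters", max(1, round(12 * area_scale)))
        kw.setdefault("n_ephemeral_waters", max(2, round(30 * area_scale)))
        # flank slopes sized so upland bells cross the TRI 17 escarpment
        # break and dune flanks land in the 3.5-17 dune/scree band
        uplands = [
            ((int(0.20 * nrow), int(0.70 * ncol)), max(6, nrow // 20), 400.0),
            ((int(0.75 * nrow), int(0.22 * ncol)), max(6, nrow // 24), 360.0),
            ((int(0.62 * nrow), int(0.80 * ncol)), max(6, nrow // 24), 380.0),
        ]
        dunes = [(30.0, 300.0, 25.0)]
        return cls(shape=shape, seed=seed, upland_blocks=uplands, dune_ridges=dunes, **kw)

    def transform(self) -> GridTransform:
        d = self.cell_size_m
        return GridTransform(x0=0.0, y0=self.shape[0] * d, dx=d, dy=-d)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def _cell_centers_m(cfg: LandscapeConfig) -> tuple[np.ndarray, np.ndarray]:
    nrow, ncol = cfg.shape
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    return cfg.transform().cell_center(rows, cols)


def generate_dem(cfg: LandscapeConfig) -> GridRaster:
    """DEM = flat base + dune-ridge sinusoids + cosine-bell upland blocks.

    Closed form and fully deterministic; with no dunes and no uplands the
    surface is a constant ``base_elevation_m``.
    """
    x, y = _cell_centers_m(cfg)
    z = np.full(cfg.shape, float(cfg.base_elevation_m))
    for theta_deg, wavelength_m, amplitude_m in cfg.dune_ridges:
        th = np.deg2rad(float(theta_deg))
        phase = 2 * np.pi * (x * np.cos(th) + y * np.sin(th)) / float(wavelength_m)
        z += float(amplitude_m) * 0.5 * (1 + np.sin(phase))
    d = cfg.cell_size_m
    rows, cols = np.meshgrid(np.arange(cfg.shape[0]), np.arange(cfg.shape[1]), indexing="ij")
    for (crow, ccol), radius_cells, height_m in cfg.upland_blocks:
        r = np.hypot(rows - float(crow), cols - float(ccol))
        inside = r <= float(radius_cells)
        z = np.where(
            inside,
            z + float(height_m) * 0.5 * (1 + np.cos(np.pi * r / float(radius_cells))),
            z,
        )
    return GridRaster(values=z, transform=cfg.transform(), band_meaning="elevation m")


def _water_sites(cfg: LandscapeConfig, dem: GridRaster) -> tuple[np.ndarray, np.ndarray]:
    """Choose distinct cells for persistent then ephemeral waters.

    Water pools in low terrain, so sites are drawn from cells at or below
    the landscape's median elevation (all cells when the DEM is flat).
    """
    rng = cfg._rng(_STREAM_WATER)
    z = dem.values.ravel()
    low = np.flatnonzero(z <= np.nanmedian(z))
    n = cfg.n_persistent_waters + cfg.n_ephemeral_waters
    if n == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    if low.size < n:
        low = np.flatnonzero(~np.isnan(z))
    if low.size < n:
        raise ValueError("more water points requested than available cells")
    picks = rng.choice(low, size=n, replace=False)
    return picks[: cfg.n_persistent_waters], picks[cfg.n_persistent_waters :]


def generate_water_occurrence(cfg: LandscapeConfig, dem: GridRaster) -> GridRaster:
    """Surface-water occurrence (%): persistent in (20, 90], ephemeral in (0, 5].

    Background is 0 %.  Every persistent site strictly exceeds the 5.0 %
    detection cut and every ephemeral site is at or below it, so the
    downstream threshold has an exactly known survivor set.
    """
    persist, ephem = _water_sites(cfg, dem)
    rng = cfg._rng(_STREAM_WATER).spawn(1)[0]  # occurrence draws, after placement
    occ = np.zeros(cfg.shape).ravel()
    if persist.size:
        occ[persist] = rng.uniform(*_PERSISTENT_OCC, size=persist.size)
    if ephem.size:
        occ[ephem] = rng.uniform(*_EPHEMERAL_OCC, size=ephem.size)
    return GridRaster(
        values=occ.reshape(cfg.shape),
        transform=dem.transform,
        band_meaning="water-occurrence %",
    )


def generate_ndvi_stack(
    cfg: LandscapeConfig, dem: GridRaster, water: GridRaster
) -> list[GridRaster]:
    """Seasonal NDVI stack, greener near persistent water.

    NDVI(t) = base + seasonal sinusoid + water-proximity boost + noise,
    clipped to [-1, 1].  The boost tapers linearly from full at a detected
    (> 5 %) water cell to zero at ``ndvi_boost_radius_m``, emulating the
    greener-near-water gradient of real arid landscapes.
    """
    if cfg.ndvi_timesteps < 1:
        raise ValueError("ndvi_timesteps must be >= 1")
    rng = cfg._rng(_STREAM_NDVI)
    x, y = _cell_centers_m(cfg)
    wet = water.values > 5.0
    boost = np.zeros(cfg.shape)
    if wet.any() and cfg.ndvi_water_boost > 0:
        wx, wy = x[wet], y[wet]
        # distance to nearest detected water cell (site counts are small)
        d2 = np.full(cfg.shape, np.inf)
        for xi, yi in zip(wx, wy):
            d2 = np.minimum(d2, (x - xi) ** 2 + (y - yi) ** 2)
        dist = np.sqrt(d2)
        boost = cfg.ndvi_water_boost * np.clip(1 - dist / cfg.ndvi_boost_radius_m, 0, 1)
    stack = []
    T = cfg.ndvi_timesteps
    for t in range(T):
        season = cfg.ndvi_seasonal_amplitude * np.sin(2 * np.pi * t / max(T, 2))
        vals = cfg.ndvi_base + season + boost
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
        stack.append(
            GridRaster(
                values=np.clip(vals, -1.0, 1.0),
                transform=dem.transform,
                band_meaning=f"NDVI t={t}",
            )
        )
    return stack


def generate_zones(cfg: LandscapeConfig, k: int | None = None) -> ZoneRaster:
    """Partition the grid into k rectangular zones labelled 1..k.

    The factorization closest to square is used (k = 4 on a 10x10 grid gives
    four 5x5 blocks); k must not exceed the cell count.
    """
    nrow, ncol = cfg.shape
    k = cfg.n_zones if k is None else int(k)
    if k < 1 or k > nrow * ncol:
        raise ValueError(f"k={k} zones impossible on a {nrow}x{ncol} grid")
    kr = max(d for d in range(1, int(np.sqrt(k)) + 1) if k % d == 0)
    kc = k // kr
    if kr > nrow or kc > ncol:
        kr, kc = (k, 1) if k <= nrow else (1, k)
        if kr > nrow or kc > ncol:
            raise ValueError(f"cannot tile {k} zones on a {nrow}x{ncol} grid")
    row_band = np.minimum(np.arange(nrow) * kr // nrow, kr - 1)
    col_band = np.minimum(np.arange(ncol) * kc // ncol, kc - 1)
    ids = (row_band[:, None] * kc + col_band[None, :] + 1).astype(np.int32)
    labels = {i: f"Z{i:02d}" for i in range(1, k + 1)}
    return ZoneRaster(zone_ids=ids, transform=cfg.transform(), labels=labels)
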