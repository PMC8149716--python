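"""Fuzzy linear rescaling and the greenness / ruggedness derived variables.

The suitability model rescales each physical input onto [0, 1] with a
two-anchor clamped linear membership function:

* walking time to water, anchored 0 h -> 1, 16 h -> 0 (see :mod:`walktime`);
* 95th-percentile NDVI composite, anchored 0.0 -> 0, 0.3 -> 1;
* terrain ruggedness index (TRI), anchored 0 -> 1, 17 -> 0.

Anchors follow the printed worked values of the source analysis: 8 h -> 0.5,
NDVI 0.15 -> 0.5, TRI 8.5 -> 0.5.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .raster import GridRaster, assert_aligned

__all__ = [
    "FuzzyLinearSpec",
    "fuzzy_linear",
    "WATER_ACCESS_SPEC",
    "GREENNESS_SPEC",
    "RUGGEDNESS_SPEC",
    "ndvi",
    "percentile_composite",
    "NDVIComposite",
    "greenness_membership",
    "tri",
    "TRIField",
    "ruggedness_membership",
]


@dataclasses.dataclass(frozen=True)
class FuzzyLinearSpec:
    """Two-anchor linear membership: ``x_full`` maps to 1, ``x_zero`` to 0.

    Direction (increasing or decreasing) is implied by the anchor order;
    values beyond the anchors clamp to the nearer endpoint.
    """

    x_full: float
    x_zero: float

    def __post_init__(self) -> None:
        if self.x_full == self.x_zero:
            raise ValueError("degenerate fuzzy spec: x_full == x_zero")


# the model's three rescalings
WATER_ACCESS_SPEC = FuzzyLinearSpec(x_full=0.0, x_zero=16.0)   # hours walk to water
GREENNESS_SPEC = FuzzyLinearSpec(x_full=0.3, x_zero=0.0)       # NDVI
RUGGEDNESS_SPEC = FuzzyLinearSpec(x_full=0.0, x_zero=17.0)     # TRI, meters


def fuzzy_linear(x, spec: FuzzyLinearSpec):
    """Clamped linear membership of ``x`` under ``spec``; works elementwise.

    NaN passes through (nodata propagation); +/-inf maps to the clamped end.
    """
    x = np.asarray(x, dtype=np.float64)
    m = (x - spec.x_zero) / (spec.x_full - spec.x_zero)
    out = np.clip(m, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclasses.dataclass
class NDVIComposite:
    """Per-cell percentile composite of an NDVI time stack."""

    raster: GridRaster
    n_timesteps: int
    percentile: float = 95.0

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


@dataclasses.dataclass
class TRIField:
    """Terrain ruggedness index (meters), 3x3 neighborhood."""

    raster: GridRaster
    neighborhood: int = 3

    @property
    def values(self) -> np.ndarray:
        return self.raster.values


def ndvi(nir: GridRaster, red: GridRaster) -> GridRaster:
    """NDVI = (NIR - Red) / (NIR + Red), elementwise on aligned bands.

    Zero total reflectance (NIR + Red == 0) has no defined ratio -> nodata.
    """
    assert_aligned([nir, red], ["nir", "red"])
    if np.nanmin(nir.values) < 0 or np.nanmin(red.values) < 0:
        raise ValueError("reflectance must be non-negative")
    total = nir.values + red.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (nir.values - red.values) / total, np.nan)
    return nir.with_values(out, band_meaning="NDVI")


def percentile_composite(stack: list[GridRaster], q: float = 95.0) -> NDVIComposite:
    """Per-cell qth percentile over valid observations of an aligned stack.

    Linear interpolation between closest order statistics (the default of
    the source platform's percentile reducer); a cell with zero valid
    observations is nodata.  No gap-filling.
    """
    if len(stack) == 0:
        raise ValueError("empty NDVI stack")
    if len(stack) > 1:
        assert_aligned(stack, [f"stack[{i}]" for i in range(len(stack))])
    cube = np.stack([r.values for r in stack], axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells -> NaN
        comp = np.nanpercentile(cube, q, axis=0, method="linear")
    raster = stack[0].with_values(comp, band_meaning=f"NDVI p{q:g} composite")
    return NDVIComposite(raster=raster, n_timesteps=len(stack), percentile=q)


def greenness_membership(comp: NDVIComposite, spec: FuzzyLinearSpec = GREENNESS_SPEC) -> GridRaster:
    """var2: fuzzy greenness membership of the NDVI composite.

    NDVI >= 0.3 is fully green (healthy arid-zone vegetation); NDVI <= 0.0
    is bare earth, membership 0.
    """
    return comp.raster.with_values(fuzzy_linear(comp.values, spec), band_meaning="var2 greenness membership")


def tri(dem: GridRaster, method: str = "mean_abs") -> TRIField:
    """Terrain ruggedness index of a DEM over the 3x3 neighborhood.

    ``mean_abs`` (default): mean absolute elevation difference between the
    center cell and its available neighbors — edge cells use the neighbors
    they have, nodata neighbors are excluded, and a cell with no valid
    neighbor is nodata.  ``rss``: the root-sum-of-squares convention.
    """
    if method not in ("mean_abs", "rss"):
        raise ValueError(f"unknown TRI method {method!r}")
    z = dem.values
    nrow, ncol = z.shape
    pad = np.pad(z, 1, constant_values=np.nan)
    acc = np.zeros((nrow, ncol))
    cnt = np.zeros((nrow, ncol))
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb = pad[1 + dr : 1 + dr + nrow, 1 + dc : 1 + dc + ncol]
            diff = nb - z
            ok = ~np.isnan(diff)
            d = np.where(ok, diff, 0.0)
            acc += d * d if method == "rss" else np.abs(d)
            cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "rss":
            out = np.sqrt(acc)
        else:
            out = acc / cnt
    out = np.where((cnt == 0) | np.isnan(z), np.nan, out)
    raster = dem.with_values(out, band_meaning="TRI m")
    return TRIField(raster=raster)


def ruggedness_membership(t: TRIField, spec: FuzzyLinearSpec = RUGGEDNESS_SPEC) -> GridRaster:
    """var3: fuzzy traversability membership of the TRI surface.

    Flat terrain (TRI 0) has membership 1; escarpments and uplands
    (TRI >= 17) have membership 0.
    """
    return t.raster.with_values(fuzzy_linear(t.values, spec), band_meaning="var3 ruggedness membership")
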