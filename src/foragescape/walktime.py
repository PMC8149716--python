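"""Walking time to the nearest detected water cell under Tobler's hiking function.

The water-accessibility variable (var1) needs, for every grid cell, the
minimal time in hours a forager would spend walking from that cell to any
cell where surface water is detected.  Travel cost is anisotropic: Tobler's
empirical hiking function

    speed(s) = 6 * exp(-3.5 * |s + 0.05|)   [km/h]

with s the signed slope (rise/run) along the direction of travel, is fastest
on a gentle -5 % downhill and penalises both climbs and steep descents.  The
accumulation is an exact multi-source shortest path over the 8- (or 16-)
connected grid graph, with slopes signed cell -> water (the forager leaves
the foraging patch and walks to water).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .raster import GridRaster, assert_aligned
from .variables import FuzzyLinearSpec, WATER_ACCESS_SPEC, fuzzy_linear

__all__ = [
    "BinaryWaterMask",
    "WalkTimeField",
    "threshold_water",
    "tobler_speed",
    "walking_time",
    "water_accessibility",
    "BASE_SPEED_KMH",
    "FLAT_SPEED_KMH",
]

BASE_SPEED_KMH = 6.0
#: walking speed on perfectly flat ground, 6*exp(-0.175) ~ 5.037 km/h
FLAT_SPEED_KMH = BASE_SPEED_KMH * math.exp(-3.5 * 0.05)

_OFFSETS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
_OFFSETS_16 = _OFFSETS_8 + [
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
]


@dataclasses.dataclass
class BinaryWaterMask:
    """Detected-water raster: 1 = water, 0 = dry, NaN = nodata."""

    values: np.ndarray
    transform: "object"
    threshold_pct: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_water(self) -> int:
        return int(np.nansum(self.values))


@dataclasses.dataclass
class WalkTimeField:
    """Hours of walking to nearest water; +inf = unreachable, NaN = nodata."""

    hours: np.ndarray
    transform: "object"
    connectivity: int = 8
    speed_model: str = "tobler"

    @property
    def shape(self) -> tuple[int, int]:
        return self.hours.shape  # type: ignore[return-value]

    @property
    def n_unreachable(self) -> int:
        return int(np.isinf(self.hours).sum())


def threshold_water(occurrence: GridRaster, cutoff: float = 5.0) -> BinaryWaterMask:
    """Binary water mask: 1 where occurrence is *strictly* greater than cutoff.

    The source product records, per cell, the percentage of satellite
    observations in which surface water was detected; cells seen wet in more
    than 5.0 % of observations count as detected water, everything at or
    below the cutoff (ephemeral puddles, noise) does not.
    """
    v = occurrence.values
    with np.errstate(invalid="ignore"):
        if np.nanmin(v) < 0 or np.nanmax(v) > 100:
            raise ValueError("occurrence must be a percentage in [0, 100]")
    out = np.where(np.isnan(v), np.nan, (v > cutoff).astype(np.float64))
    return BinaryWaterMask(values=out, transform=occurrence.transform, threshold_pct=cutoff)


def tobler_speed(slope):
    """Walking speed (km/h) at signed slope ``slope`` = rise/run.

    Maximal (6 km/h) at slope -0.05; symmetric about that point.
    """
    s = np.asarray(slope, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("slope must be finite")
    v = BASE_SPEED_KMH * np.exp(-3.5 * np.abs(s + 0.05))
    return float(v) if v.ndim == 0 else v


def _edge_list(dem: GridRaster, connectivity: int):
    """Directed edges (u, v, hours) of the travel graph over valid cells.

    Edge u -> v is one step of travel from cell u to neighbor v; its cost is
    horizontal distance / tobler_speed(signed slope along u -> v).
    """
    offsets = {8: _OFFSETS_8, 16: _OFFSETS_16}.get(connectivity)
    if offsets is None:
        raise ValueError("connectivity must be 8 or 16")
    t = dem.transform
    if not math.isclose(t.dx, abs(t.dy), rel_tol=1e-9):
        raise ValueError("walking time requires square cells (dx == |dy|)")
    z = dem.values
    nrow, ncol = z.shape
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    valid = ~np.isnan(z)
    rows_u, cols_u, rows_v, cols_v, hours = [], [], [], [], []
    for dr, dc in offsets:
        r0a, r0b = max(0, -dr), min(nrow, nrow - dr)
        c0a, c0b = max(0, -dc), min(ncol, ncol - dc)
        if r0a >= r0b or c0a >= c0b:
            continue
        u = idx[r0a:r0b, c0a:c0b]
        v = idx[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
        ok = valid[r0a:r0b, c0a:c0b] & valid[r0a + dr : r0b + dr, c0a + dc : c0b + dc]
        u, v = u[ok], v[ok]
        if u.size == 0:
            continue
        dist_m = math.hypot(dr * t.dy, dc * t.dx)
        dz = z.ravel()[v] - z.ravel()[u]
        speed = BASE_SPEED_KMH * np.exp(-3.5 * np.abs(dz / dist_m + 0.05))
        hours.append((dist_m / 1000.0) / speed)
        rows_u.append(u)
        rows_v.append(v)
    if not rows_u:
        return (np.array([], dtype=np.int64),) * 2 + (np.array([]),)
    return np.concatenate(rows_u), np.concatenate(rows_v), np.concatenate(hours)


def walking_time(
    dem: GridRaster,
    water: BinaryWaterMask,
    connectivity: int = 8,
    max_hours: float | None = None,
) -> WalkTimeField:
    """Minimal walking hours from every cell to its nearest water cell.

    Exact multi-source Dijkstra over the grid travel graph: all water cells
    are zero-cost sources and edge costs are Tobler travel times signed
    along the cell -> water direction of movement.  Cells that cannot reach
    any water (nodata-separated islands, or a waterless landscape) come back
    +inf; nodata cells stay NaN.  ``max_hours`` optionally truncates the
    accumulation (everything beyond maps to membership 0 anyway).
    """
    if dem.shape != water.shape:
        raise ValueError("dem and water mask are misaligned")
    assert_aligned(
        [dem, GridRaster(np.zeros(water.shape), water.transform)], ["dem", "water"]
    )
    z = dem.values
    valid = ~np.isnan(z)
    if not valid.any():
        raise ValueError("DEM has no valid cells")
    n = z.size
    src = np.flatnonzero((np.nan_to_num(water.values) == 1).ravel() & valid.ravel())
    hours = np.full(n, np.inf)
    if src.size:
        u, v, w = _edge_list(dem, connectivity)
        # shortest path cell -> water == shortest path water -> cell on the
        # direction-reversed graph, so transpose before the sweep
        graph = csr_matrix((w, (u, v)), shape=(n, n)).transpose().tocsr()
        limit = np.inf if max_hours is None else float(max_hours)
        hours = dijkstra(graph, directed=True, indices=src, min_only=True, limit=limit)
        if max_hours is not None:
            hours = np.where(hours > limit, np.inf, hours)
    hours = hours.reshape(z.shape)
    hours[~valid] = np.nan
    return WalkTimeField(hours=hours, transform=dem.transform, connectivity=connectivity)


def water_accessibility(
    time: WalkTimeField, spec: FuzzyLinearSpec = WATER_ACCESS_SPEC
) -> GridRaster:
    """var1: fuzzy water-accessibility membership of a walking-time field.

    Cells at water score 1, cells 8 h out score 0.5, anything at or beyond
    16 h (including unreachable cells) scores 0.
    """
    h = time.hours
    m = np.where(np.isinf(h), 0.0, fuzzy_linear(np.where(np.isinf(h), 0.0, h), spec))
    m = np.where(np.isnan(h), np.nan, m)
    return GridRaster(
        values=m,
        transform=time.transform,  # type: ignore[arg-type]
        band_meaning="var1 water-accessibility membership",
    )
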