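"""Grid data model and GeoTIFF/CSV plumbing shared by every pipeline stage.

All surfaces travel through the pipeline as :class:`GridRaster`: a single-band
2-D array with an affine georeference in projected meters and a nodata
sentinel.  In memory, nodata cells are NaN; on disk they are the declared
sentinel value.  Every stage requires its inputs to be *pre-aligned* (same
shape and transform); :func:`snap_to` is the explicit, never-implicit
resampling step for inputs that arrive on a shifted grid.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GridTransform",
    "GridRaster",
    "ZoneRaster",
    "AlignmentError",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "assert_aligned",
    "snap_to",
]

# GeoTIFF tag codes understood by every mainstream GIS reader.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory: version 1.1.0, one key, GTModelTypeGeoKey (1024)
# = 1 (projected CRS).  Geographic (degree) grids are rejected on read
# because the walking-time stage needs metric cell sizes.
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
_GEO_KEYS_PROJECTED = (1, 1, 0, 1, 1024, 0, 1, _MODEL_TYPE_PROJECTED)


class AlignmentError(ValueError):
    """Two rasters do not share a grid (shape or transform mismatch)."""


class RasterFormatError(ValueError):
    """A file is not a single-band georeferenced raster we can use."""


@dataclasses.dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: cell (row, col) -> projected meters.

    ``x0, y0`` is the outer corner of the upper-left cell; ``dx > 0`` and
    ``dy < 0`` (rows increase southwards) are cell sizes in meters.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and abs(self.dy) > 0):
            raise ValueError(f"cell sizes must be nonzero, dx>0 (got dx={self.dx}, dy={self.dy})")

    @property
    def cell_size_m(self) -> float:
        return float(self.dx)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected coordinates of cell centers."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col containing projected points (floor convention)."""
        col = np.floor((np.asarray(x) - self.x0) / self.dx).astype(np.int64)
        row = np.floor((np.asarray(y) - self.y0) / self.dy).astype(np.int64)
        return row, col

    def almost_equals(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            math.isclose(self.x0, other.x0, abs_tol=tol)
            and math.isclose(self.y0, other.y0, abs_tol=tol)
            and math.isclose(self.dx, other.dx, abs_tol=tol)
            and math.isclose(self.dy, other.dy, abs_tol=tol)
        )


@dataclasses.dataclass
class GridRaster:
    """A single-band raster: float payload, NaN-as-nodata in memory.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    transform
        Georeference of the grid (projected meters).
    nodata
        Sentinel written to disk for NaN cells (default -9999).
    band_meaning
        Free-text tag describing the physical quantity, e.g. "NDVI",
        "elevation m", "water-occurrence %".
    """

    values: np.ndarray
    transform: GridTransform
    nodata: float = -9999.0
    band_meaning: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("empty raster")
        # sentinel-coded inputs are normalised to NaN immediately
        self.values = np.where(self.values == self.nodata, np.nan, self.values)
        with np.errstate(invalid="ignore"):
            if np.isinf(self.values).any():
                raise ValueError("raster values must be finite where not nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where nodata."""
        return np.isnan(self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def cell_size_m(self) -> float:
        return self.transform.cell_size_m

    @property
    def cell_area_km2(self) -> float:
        return self.transform.dx * abs(self.transform.dy) / 1e6

    def with_values(self, values: np.ndarray, band_meaning: str | None = None) -> "GridRaster":
        """A new raster on the same grid with a different payload."""
        return GridRaster(
            values=np.asarray(values, dtype=np.float64),
            transform=self.transform,
            nodata=self.nodata,
            band_meaning=self.band_meaning if band_meaning is None else band_meaning,
        )

    def aligned_with(self, other: "GridRaster | ZoneRaster") -> bool:
        return self.shape == other.shape and self.transform.almost_equals(other.transform)


@dataclasses.dataclass
class ZoneRaster:
    """Integer zone labels on the common grid; 0 = outside the study area."""

    zone_ids: np.ndarray
    transform: GridTransform
    labels: dict[int, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zone_ids = np.asarray(self.zone_ids)
        if not np.issubdtype(self.zone_ids.dtype, np.integer):
            raise ValueError("zone_ids must be integers")
        if self.zone_ids.ndim != 2:
            raise ValueError("zone_ids must be 2-D")
        if (self.zone_ids < 0).any():
            raise ValueError("zone_ids must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.zone_ids.shape  # type: ignore[return-value]

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero zone ids present in the raster."""
        u = np.unique(self.zone_ids)
        return u[u > 0]

    def label(self, zone_id: int) -> str:
        return self.labels.get(int(zone_id), f"zone_{int(zone_id)}")


def _transform_from_tags(page: "tifffile.TiffPage", path: Path) -> GridTransform:
    tags = page.tags
    scale = tags.get(_TAG_PIXEL_SCALE)
    tie = tags.get(_TAG_TIEPOINT)
    if scale is None or tie is None:
        raise RasterFormatError(f"{path}: missing georeference (pixel scale / tiepoint tags)")
    sx, sy = float(scale.value[0]), float(scale.value[1])
    # tiepoint: raster (i, j, k) -> model (x, y, z); we require the (0,0) corner
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    x0 = x - i * sx
    y0 = y + j * sy
    geo = tags.get(_TAG_GEO_KEYS)
    if geo is not None:
        keys = np.asarray(geo.value).ravel()
        for k in range(4, len(keys) - 3, 4):
            if keys[k] == 1024 and keys[k + 3] == _MODEL_TYPE_GEOGRAPHIC:
                raise RasterFormatError(
                    f"{path}: geographic (degree) grid; this pipeline needs projected meters"
                )
    return GridTransform(x0=x0, y0=y0, dx=sx, dy=-sy)


def read_raster(path: str | Path, band_meaning: str = "") -> GridRaster:
    """Read a single-band georeferenced GeoTIFF as a :class:`GridRaster`.

    Multi-band files and files without georeferencing tags are rejected; the
    GDAL nodata tag, when present, is honored (those cells come back NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[..., 0]
        if arr.ndim != 2 or len(tif.pages) > 1:
            raise RasterFormatError(f"{path}: expected a single band, got multi-band data")
        transform = _transform_from_tags(page, path)
        nodata = -9999.0
        nd_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nd_tag is not None:
            nodata = float(str(nd_tag.value).strip().strip("\x00"))
        desc = page.tags.get("ImageDescription")
        meaning = band_meaning or (str(desc.value) if desc is not None else "")
    return GridRaster(values=arr.astype(np.float64), transform=transform, nodata=nodata, band_meaning=meaning)


def write_raster(r: GridRaster, path: str | Path, dtype: str = "float32") -> None:
    """Write a GeoTIFF (single band) with georeference and nodata header.

    ``dtype`` may be ``float32`` (continuous surfaces) or ``uint8`` /
    ``uint16`` (masks, classes, zones); float payloads round-trip
    bit-faithfully at float32 precision.
    """
    path = Path(path)
    t = r.transform
    if dtype == "float32":
        out = np.where(np.isnan(r.values), r.nodata, r.values).astype(np.float32)
        nodata_str = repr(float(r.nodata))
    elif dtype in ("uint8", "uint16"):
        cap = 255 if dtype == "uint8" else 65535
        sentinel = cap  # integer rasters use the dtype maximum as nodata
        filled = np.where(np.isnan(r.values), sentinel, r.values)
        out = np.clip(np.round(filled), 0, cap).astype(dtype)
        nodata_str = str(sentinel)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, abs(t.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS_PROJECTED), _GEO_KEYS_PROJECTED),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(
        path,
        out,
        photometric="minisblack",
        extratags=extratags,
        description=r.band_meaning or None,
        metadata=None,
    )


def write_zone_raster(z: ZoneRaster, path: str | Path) -> None:
    """Write zones as uint16 GeoTIFF (0 stays 0: outside study area)."""
    r = GridRaster(values=z.zone_ids.astype(np.float64), transform=z.transform, nodata=65535.0)
    write_raster(r, path, dtype="uint16")


def read_zone_raster(path: str | Path, labels: dict[int, str] | None = None) -> ZoneRaster:
    r = read_raster(path)
    ids = np.where(np.isnan(r.values), 0, r.values).astype(np.int32)
    return ZoneRaster(zone_ids=ids, transform=r.transform, labels=labels or {})


def assert_aligned(rasters: list, names: list[str] | None = None) -> None:
    """Raise :class:`AlignmentError` unless all rasters share shape and transform.

    Reflexive and symmetric: order of the list does not matter; the first
    raster is the reference and the offending raster is named in the error.
    """
    if len(rasters) < 2:
        raise ValueError("assert_aligned needs at least two rasters")
    names = names or [f"raster[{i}]" for i in range(len(rasters))]
    ref = rasters[0]
    for r, name in zip(rasters[1:], names[1:]):
        if r.shape != ref.shape:
            raise AlignmentError(
                f"{name}: shape {r.shape} does not match {names[0]} shape {ref.shape}"
            )
        if not ref.transform.almost_equals(r.transform):
            raise AlignmentError(
                f"{name}: transform {r.transform} does not match {names[0]} transform {ref.transform}"
            )


def snap_to(reference: GridRaster, r: GridRaster, method: str = "nearest") -> GridRaster:
    """Resample ``r`` onto ``reference``'s grid by nearest neighbor.

    Cells of the reference grid whose centers fall outside ``r``'s extent
    become nodata.  Disjoint extents are an error.  This is the explicit
    "snap raster" preprocessing step; no pipeline stage resamples silently.
    """
    if method != "nearest":
        raise ValueError("only nearest-neighbor snapping is supported")
    nrow, ncol = reference.shape
    rows, cols = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    x, y = reference.transform.cell_center(rows, cols)
    src_row, src_col = r.transform.index_of(x, y)
    inside = (
        (src_row >= 0) & (src_row < r.shape[0]) & (src_col >= 0) & (src_col < r.shape[1])
    )
    if not inside.any():
        raise AlignmentError("snap_to: extents are disjoint (no reference cell falls inside r)")
    out = np.full(reference.shape, np.nan)
    out[inside] = r.values[src_row[inside], src_col[inside]]
    return GridRaster(
        values=out,
        transform=reference.transform,
        nodata=r.nodata,
        band_meaning=r.band_meaning,
    )
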