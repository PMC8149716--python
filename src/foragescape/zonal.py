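"""Per-zone and per-class summary tables of a value raster.

Mirrors the "zonal statistics as table" step: for every (zone, suitability
class) group of unmasked cells, the pixel count, land area in km², and the
mean / min / max / standard deviation of a chosen value raster (typically
the NDVI composite).  Cells belong wholly to the zone of their cell center.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import GridRaster, ZoneRaster
from .suitability import CLASS_NAMES, SuitabilityClassField, SuitabilityField

__all__ = ["zonal_table", "class_area_percent"]

_COLUMNS = [
    "zone_id", "zone_label", "class", "n_cells", "area_km2", "mean", "min", "max", "sd",
]


def _group_stats(vals: np.ndarray, ddof: int) -> tuple:
    if vals.size == 0:
        return (np.nan, np.nan, np.nan, np.nan)
    sd = float(vals.std(ddof=ddof)) if vals.size > ddof else np.nan
    return (float(vals.mean()), float(vals.min()), float(vals.max()), sd)


def zonal_table(
    value: GridRaster,
    zones: ZoneRaster,
    classes: SuitabilityClassField | None = None,
    mask_field: SuitabilityField | None = None,
    sd_ddof: int = 0,
) -> pd.DataFrame:
    """Summary statistics of ``value`` grouped by zone (and class, if given).

    Only unmasked, valid cells count; empty groups are emitted with
    ``n_cells = 0`` and null moments.  ``sd_ddof=0`` gives the population
    standard deviation (the source tool's convention); 1 gives the sample
    form.  With ``classes`` present each zone also gets an "all" row.
    """
    if value.shape != zones.shape:
        raise ValueError("value raster and zone raster are misaligned")
    if not value.transform.almost_equals(zones.transform):
        raise ValueError("value raster and zone raster transforms differ")
    ok = value.valid
    if mask_field is not None:
        if mask_field.raster.shape != value.shape:
            raise ValueError("mask field misaligned with value raster")
        ok &= mask_field.unmasked
    if classes is not None and classes.shape != value.shape:
        raise ValueError("class raster misaligned with value raster")

    cell_km2 = value.cell_area_km2
    records = []
    for zid in zones.ids:
        in_zone = (zones.zone_ids == zid) & ok
        groups: list[tuple[str, np.ndarray]] = [("all", in_zone)]
        if classes is not None:
            groups += [
                (CLASS_NAMES[c], in_zone & (classes.classes == c))
                for c in sorted(CLASS_NAMES)
            ]
        for cname, sel in groups:
            vals = value.values[sel]
            n = int(sel.sum())
            mean, vmin, vmax, sd = _group_stats(vals, sd_ddof)
            records.append(
                (int(zid), zones.label(zid), cname, n, n * cell_km2, mean, vmin, vmax, sd)
            )
    return pd.DataFrame.from_records(records, columns=_COLUMNS)


def class_area_percent(
    classes: SuitabilityClassField,
    zones: ZoneRaster,
    mask_field: SuitabilityField | None = None,
    cell_area_km2: float | None = None,
) -> pd.DataFrame:
    """Land area and percentage of low/moderate/high per zone, plus a whole-area row.

    Percentages are of each zone's *unmasked* classified area, so the three
    classes sum to 100 within every zone with any classified cells.  The
    whole-study-area row carries ``zone_id = 0`` and label "ALL".
    """
    if classes.shape != zones.shape:
        raise ValueError("class raster and zone raster are misaligned")
    if cell_area_km2 is None:
        t = zones.transform
        cell_area_km2 = t.dx * abs(t.dy) / 1e6
    cls = classes.classes
    classified = cls > 0
    if mask_field is not None:
        classified &= mask_field.unmasked

    def rows_for(sel: np.ndarray, zid: int, label: str):
        total = int(sel.sum())
        out = []
        for c in sorted(CLASS_NAMES):
            n = int((sel & (cls == c)).sum())
            pct = 100.0 * n / total if total else 0.0
            out.append((zid, label, CLASS_NAMES[c], n, n * cell_area_km2, pct))
        return out

    records = []
    for zid in zones.ids:
        records += rows_for(classified & (zones.zone_ids == zid), int(zid), zones.label(zid))
    records += rows_for(classified, 0, "ALL")
    return pd.DataFrame.from_records(
        records, columns=["zone_id", "zone_label", "class", "n_cells", "area_km2", "percent"]
    )
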