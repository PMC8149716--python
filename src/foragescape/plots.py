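"""Figures for a completed run: class map, S histogram, class areas, NDVI boxes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import ForagingHabitatResults
from .suitability import CLASS_NAMES

__all__ = ["plot_results"]

_CLASS_COLORS = {1: "#d73027", 2: "#fee08b", 3: "#1a9850"}  # low/moderate/high


def plot_results(res: ForagingHabitatResults, out_dir: str | Path) -> list[Path]:
    """Write the four standard figures; returns the created file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [
        _class_map(res, out / "class_map.png"),
        _s_histogram(res, out / "s_histogram.png"),
        _class_area_bars(res, out / "class_areas.png"),
        _ndvi_boxplot(res, out / "ndvi_by_class.png"),
    ]
    return paths


def _class_map(res, path: Path) -> Path:
    cls = res.classes.classes.astype(float)
    cls[cls == 0] = np.nan
    cmap = matplotlib.colors.ListedColormap([_CLASS_COLORS[c] for c in (1, 2, 3)])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(cls, cmap=cmap, vmin=1, vmax=3, interpolation="nearest")
    ax.set_title("Foraging habitat suitability classes")
    ax.set_axis_off()
    handles = [
        matplotlib.patches.Patch(color=_CLASS_COLORS[c], label=CLASS_NAMES[c]) for c in (1, 2, 3)
    ]
    ax.legend(handles=handles, loc="lower left", fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _s_histogram(res, path: Path) -> Path:
    vals = res.suitability.unmasked_values
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vals, bins=60, color="#74add1", edgecolor="none")
    for b in res.breaks.breaks:
        ax.axvline(b, color="k", linestyle="--", linewidth=1)
        ax.annotate(f"{b:.3f}", (b, ax.get_ylim()[1] * 0.95), fontsize=8, ha="left")
    ax.set_xlabel("suitability S")
    ax.set_ylabel("cells")
    ax.set_title(f"S distribution with Jenks breaks (gvf={res.gvf:.3f})")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _class_area_bars(res, path: Path) -> Path:
    areas = res.class_areas()
    zones = areas[areas.zone_id > 0]
    if zones.empty:
        zones = areas
    piv = zones.pivot_table(index="zone_label", columns="class", values="percent")
    piv = piv.reindex(columns=["low", "moderate", "high"]).fillna(0.0)
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(piv))
    for c, name in CLASS_NAMES.items():
        vals = piv[name].to_numpy()
        ax.bar(piv.index, vals, bottom=bottom, color=_CLASS_COLORS[c], label=name)
        bottom += vals
    ax.set_ylabel("% of unmasked zone area")
    ax.set_title("Class share per zone")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=45)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def _ndvi_boxplot(res, path: Path) -> Path:
    cls = res.classes.classes
    comp = res.ndvi_composite.values
    ok = res.suitability.unmasked
    data, labels = [], []
    for c, name in CLASS_NAMES.items():
        sel = ok & (cls == c)
        data.append(comp[sel] if sel.any() else np.array([np.nan]))
        labels.append(name)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel("95th-percentile NDVI")
    ax.set_title("Greenness composite by suitability class")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
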