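"""Combining the fuzzy variables into the suitability surface S and classifying it.

S is the equal-weight mean of the three membership rasters,

    S = (var1 + var2 + var3) / N,    N = 3,

computed per cell on [0, 1].  Before break fitting and any statistics, open
water (raw occurrence > 5 %) and montane uplands (raw TRI > 17) are masked
out: water cells are not foraging patches, and uplands are treated as
permanently suitable refugia outside the model.  The masked S population is
then clustered into low / moderate / high classes at its Jenks natural
breaks.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .jenks import ClassBreaks, jenks_breaks
from .raster import GridRaster, assert_aligned
from .variables import TRIField

__all__ = [
    "MaskReason",
    "SuitabilityField",
    "SuitabilityClassField",
    "correlation_matrix",
    "combine",
    "apply_masks",
    "classify",
    "distribution_summary",
    "jenks_breaks",
    "ClassBreaks",
    "CLASS_LOW",
    "CLASS_MODERATE",
    "CLASS_HIGH",
    "CLASS_NAMES",
]

CLASS_LOW, CLASS_MODERATE, CLASS_HIGH = 1, 2, 3
CLASS_NAMES = {CLASS_LOW: "low", CLASS_MODERATE: "moderate", CLASS_HIGH: "high"}

WATER_MASK_CUTOFF_PCT = 5.0
UPLAND_MASK_CUTOFF_TRI = 17.0


class MaskReason(enum.IntEnum):
    NONE = 0
    OPEN_WATER = 1
    MONTANE_UPLAND = 2
    NODATA = 3


@dataclasses.dataclass
class SuitabilityField:
    """Per-cell suitability S in [0, 1] with per-cell masking provenance."""

    raster: GridRaster
    weights: tuple[float, float, float]
    masked_reason: np.ndarray  # MaskReason codes, uint8

    @property
    def S(self) -> np.ndarray:
        return self.raster.values

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean: cells that participate in statistics and break fitting."""
        return (self.masked_reason == MaskReason.NONE) & ~np.isnan(self.S)

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.S[self.unmasked]


@dataclasses.dataclass
class SuitabilityClassField:
    """Classified suitability: 1 = low, 2 = moderate, 3 = high, 0 = masked/nodata."""

    classes: np.ndarray  # uint8
    transform: "object"
    breaks: ClassBreaks

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]

    def count(self, cls: int) -> int:
        return int((self.classes == cls).sum())


def correlation_matrix(var1: GridRaster, var2: GridRaster, var3: GridRaster) -> np.ndarray:
    """Pairwise Pearson correlations of the three variables over jointly valid cells.

    The model assumes the inputs are near-independent; this is the check.
    Zero variance in any input makes its correlations undefined — that is an
    error (flagged), never silently zero.
    """
    assert_aligned([var1, var2, var3], ["var1", "var2", "var3"])
    stack = np.stack([v.values.ravel() for v in (var1, var2, var3)])
    joint = ~np.isnan(stack).any(axis=0)
    if joint.sum() < 2:
        raise ValueError("need at least 2 jointly valid cells for a correlation")
    x = stack[:, joint]
    if (x.std(axis=1) == 0).any():
        zero = [f"var{i+1}" for i in range(3) if x[i].std() == 0]
        raise ValueError(f"correlation undefined: zero variance in {', '.join(zero)}")
    return np.corrcoef(x)


def combine(
    var1: GridRaster,
    var2: GridRaster,
    var3: GridRaster,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> SuitabilityField:
    """Weighted mean of the three membership rasters; default equal weights.

    With equal weights this is exactly S = (var1 + var2 + var3) / 3.  The
    weights must lie on the simplex.  Any nodata input cell makes the output
    cell nodata.
    """
    assert_aligned([var1, var2, var3], ["var1", "var2", "var3"])
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must be 3 non-negative values summing to 1, got {weights}")
    for name, v in (("var1", var1), ("var2", var2), ("var3", var3)):
        with np.errstate(invalid="ignore"):
            if np.nanmin(v.values) < -1e-9 or np.nanmax(v.values) > 1 + 1e-9:
                raise ValueError(f"{name} membership outside [0, 1]")
    S = w[0] * var1.values + w[1] * var2.values + w[2] * var3.values
    reason = np.where(np.isnan(S), MaskReason.NODATA, MaskReason.NONE).astype(np.uint8)
    raster = var1.with_values(S, band_meaning="foraging habitat suitability S")
    return SuitabilityField(raster=raster, weights=tuple(float(x) for x in w), masked_reason=reason)


def apply_masks(
    S: SuitabilityField,
    occurrence: GridRaster,
    tri_field: TRIField,
    water_cut: float = WATER_MASK_CUTOFF_PCT,
    upland_cut: float = UPLAND_MASK_CUTOFF_TRI,
) -> SuitabilityField:
    """Mask open water and montane uplands out of the S population.

    Strict inequalities: occurrence > 5.0 % marks open water, TRI > 17 marks
    montane upland (TRI exactly 17 stays in).  The cutoffs apply to the raw
    physical scales, not the fuzzy memberships.  Must run before break
    fitting and zonal statistics.
    """
    assert_aligned([S.raster, occurrence, tri_field.raster], ["S", "occurrence", "tri"])
    reason = S.masked_reason.copy()
    with np.errstate(invalid="ignore"):
        water = occurrence.values > water_cut
        upland = tri_field.values > upland_cut
    free = reason == MaskReason.NONE
    reason[free & water] = MaskReason.OPEN_WATER
    reason[free & ~water & upland] = MaskReason.MONTANE_UPLAND
    return SuitabilityField(raster=S.raster, weights=S.weights, masked_reason=reason)


def classify(S: SuitabilityField, breaks: ClassBreaks) -> SuitabilityClassField:
    """Assign low / moderate / high classes from fitted breaks.

    Boundary rule is upper-exclusive on the low side: low is S <= b1,
    moderate is b1 < S <= b2, high is S > b2 — a value exactly at a break
    belongs to the lower class.
    """
    if breaks.k != 3:
        raise ValueError("classification expects k = 3 classes")
    b1, b2 = breaks.breaks
    if not (0.0 <= b1 < b2 <= 1.0):
        raise ValueError(f"breaks {breaks.breaks} outside [0, 1]")
    v = S.S
    cls = np.zeros(v.shape, dtype=np.uint8)
    ok = S.unmasked
    cls[ok & (v <= b1)] = CLASS_LOW
    cls[ok & (v > b1) & (v <= b2)] = CLASS_MODERATE
    cls[ok & (v > b2)] = CLASS_HIGH
    return SuitabilityClassField(classes=cls, transform=S.raster.transform, breaks=breaks)


def distribution_summary(S: SuitabilityField) -> dict:
    """Moments of the unmasked S population: mean, sd, skewness, n.

    Population standard deviation; skewness is the standardized third
    central moment, NaN (flagged) when the field is constant.
    """
    x = S.unmasked_values
    if x.size == 0:
        raise ValueError("no unmasked cells to summarize")
    mean = float(x.mean())
    sd = float(x.std())
    if sd == 0:
        skew = float("nan")
    else:
        skew = float(((x - mean) ** 3).mean() / sd**3)
    return {"mean": mean, "sd": sd, "skewness": skew, "n": int(x.size)}
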