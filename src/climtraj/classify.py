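"""Bivariate exposure classification and island exclusion.

The four-class scheme crosses velocity_MED (split at its median over valid
pixels) with MCE (split at zero: any positive exposure is "high").  Island
pixels — land components disconnected from the main landmass — are excluded
from maps and statistics because their trajectories are dominated by the
arbitrary water cost and their MCE is not interpretable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

CLASS_NODATA = 0
CLASS_LOW_V_LOW_MCE = 1
CLASS_LOW_V_HIGH_MCE = 2
CLASS_HIGH_V_LOW_MCE = 3
CLASS_HIGH_V_HIGH_MCE = 4

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def island_mask(land_mask: np.ndarray, min_island_area: int | None = None,
                connectivity: int = 8) -> np.ndarray:
    """Boolean mask of land pixels lying on islands.

    Connected components of land (8-connected by default, matching the
    routing neighbourhood); every component other than the largest counts as
    an island, or — when ``min_island_area`` is given — only components with
    fewer pixels than that.
    """
    land = np.asarray(land_mask, dtype=bool)
    labels, nlab = ndimage.label(
        land, structure=_STRUCT8 if connectivity == 8 else _STRUCT4)
    if nlab <= 1:
        return np.zeros_like(land)
    sizes = ndimage.sum_labels(land, labels, index=np.arange(1, nlab + 1))
    if min_island_area is None:
        keep = {int(np.argmax(sizes)) + 1}
    else:
        keep = {i + 1 for i, s in enumerate(sizes) if s >= min_island_area}
    out = land.copy()
    for lab in keep:
        out[labels == lab] = False
    return out


def exclude_islands(land_mask: np.ndarray, dest_row: np.ndarray,
                    dest_col: np.ndarray, source_mask: np.ndarray,
                    min_island_area: int | None = None,
                    connectivity: int = 8) -> np.ndarray:
    """Flag raster: sources on islands, or whose destination is on one.

    ``dest_row``/``dest_col`` are per-pixel destination indices (negative
    where no destination exists); ``source_mask`` marks routed sources.
    """
    isl = island_mask(land_mask, min_island_area, connectivity)
    flag = isl & np.asarray(source_mask, bool)
    src = np.asarray(source_mask, bool) & (np.asarray(dest_row) >= 0)
    rr = np.asarray(dest_row)[src]
    cc = np.asarray(dest_col)[src]
    dest_on_island = np.zeros_like(flag)
    dest_on_island[src] = isl[rr, cc]
    return flag | dest_on_island


def classify_bivariate(velocity_med: np.ndarray, mce: np.ndarray,
                       valid_mask: np.ndarray | None = None):
    """Four-class raster from the bivariate (velocity_MED, MCE) field.

    Returns ``(classes, thresholds)``.  "High" MCE means strictly positive
    (MCE = 0.0 is low regardless of velocity); "high" velocity means above
    the median of velocity_MED over valid pixels.  Flagged/invalid pixels
    are excluded from the median and classed as nodata (0).
    """
    v = np.asarray(velocity_med, dtype=float)
    m = np.asarray(mce, dtype=float)
    valid = np.isfinite(v) & np.isfinite(m)
    if valid_mask is not None:
        valid &= np.asarray(valid_mask, bool)
    if not valid.any():
        raise ValueError("no valid pixels to classify")
    v_med = float(np.median(v[valid]))
    classes = np.full(v.shape, CLASS_NODATA, dtype=np.int32)
    high_v = v > v_med
    high_m = m > 0
    classes[valid & ~high_v & ~high_m] = CLASS_LOW_V_LOW_MCE
    classes[valid & ~high_v & high_m] = CLASS_LOW_V_HIGH_MCE
    classes[valid & high_v & ~high_m] = CLASS_HIGH_V_LOW_MCE
    classes[valid & high_v & high_m] = CLASS_HIGH_V_HIGH_MCE
    thresholds = {"velocity_med_median": v_med, "mce_threshold": 0.0}
    return classes, thresholds
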