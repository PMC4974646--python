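"""Dissimilarity cost surfaces, one per 0.1 °C isotherm increment.

The cost of a pixel measures how dissimilar its temperature is from the
isotherm of interest ``T``.  Analogue pixels (within ± half_width, default
±0.25 °C) cost exactly 1, so that accumulated cost equals distance along
fully-analogue paths; beyond the analogue bin the cost rises by one integer
per full bin width (0.5 °C at the defaults):

    cost = 1                                         if |T - t| <= h
    cost = 1 + ceil((|T - t| - h) / (2 h))           otherwise

The final cost surface for an increment is the elementwise minimum of the
intermediate costs over all temporally interpolated grids — a pixel that is
an analogue of ``T`` at any time during the interval costs 1 — after which
open-water pixels are overridden to the (large) water cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import MethodParams, TemperatureGrid
from .interpolate import InterpolatedSeries

# Guards against float representation of exact band boundaries
# (e.g. a dissimilarity of 0.75 computed as 0.7500000000000002).
_BAND_EPS = 1e-9


def dissimilarity_cost(T, t_i, params: MethodParams | None = None):
    """Cost of temperature ``t_i`` relative to the increment ``T``.

    Vectorised over ``t_i``.  Band boundaries are closed above: a
    dissimilarity of exactly ``half_width`` is an analogue (cost 1) and one
    of exactly 0.75 °C (at the defaults) falls in the cost-2 band.  With
    ``cost_form="continuous"`` the linear form ``penalty*|ΔT| + 1`` is used
    instead of integer banding.
    """
    params = params or MethodParams()
    d = np.abs(np.asarray(t_i, dtype=float) - T)
    if params.cost_form == "continuous":
        return np.where(d <= params.half_width + _BAND_EPS, 1.0,
                        params.penalty * d + 1.0)
    h = params.half_width
    band = 1 + np.ceil((d - h) / (2.0 * h) - _BAND_EPS)
    cost = np.where(d <= h + _BAND_EPS, 1, band)
    if np.ndim(cost) == 0:
        return int(cost) if np.isfinite(cost) else float(cost)
    return cost.astype(np.int64) if np.isfinite(cost).all() else cost


@dataclass
class CostSurface:
    """Composite cost raster for one isotherm increment."""

    increment: float             # the 0.1 °C temperature increment T
    costs: np.ndarray            # 2D float array; NaN on nodata
    n_steps: int                 # interpolation steps used to composite

    @property
    def shape(self):
        return self.costs.shape


def build_intermediate_cost(T: float, temp_values: np.ndarray,
                            params: MethodParams | None = None,
                            nodata_mask: np.ndarray | None = None) -> np.ndarray:
    """Elementwise dissimilarity cost of one temperature field against ``T``.

    Nodata pixels propagate as NaN and never participate in routing.
    """
    params = params or MethodParams()
    cost = np.asarray(dissimilarity_cost(T, temp_values, params), dtype=float)
    if nodata_mask is None:
        nodata_mask = ~np.isfinite(np.asarray(temp_values, dtype=float))
    cost[nodata_mask] = np.nan
    return cost


def build_final_cost(T: float, series: InterpolatedSeries,
                     water_mask: np.ndarray | None = None,
                     params: MethodParams | None = None,
                     nodata_mask: np.ndarray | None = None) -> CostSurface:
    """Composite (min-over-time) cost surface for increment ``T``.

    Taking the minimum across the interpolated series lets a trajectory
    traverse a pixel at whichever time the pixel's climate is most similar
    to ``T`` — a pixel that warms through the isotherm during the interval
    costs 1 even if both endpoint temperatures are dissimilar.  Water pixels
    are overridden to ``water_cost`` after the composite, land nodata stays
    NaN (unroutable).
    """
    params = params or MethodParams()
    d = np.abs(series.grids - T)
    with np.errstate(invalid="ignore"):
        dmin = np.nanmin(d, axis=0)
    cost = np.asarray(dissimilarity_cost(T, T + dmin, params), dtype=float)
    if nodata_mask is None:
        nodata_mask = ~np.isfinite(dmin)
    cost[nodata_mask] = np.nan
    if water_mask is not None:
        cost[np.asarray(water_mask, bool) & ~nodata_mask] = params.water_cost
    return CostSurface(increment=T, costs=cost, n_steps=len(series))


def enumerate_increments(current: TemperatureGrid,
                         params: MethodParams | None = None) -> np.ndarray:
    """Distinct rounded temperatures among land source pixels, ascending.

    Each source pixel belongs to exactly one increment — its own rounded
    value — so the increments partition the sources; one routing problem is
    solved per increment.
    """
    params = params or MethodParams()
    land = current.land_mask
    if not land.any():
        raise ValueError("empty land mask: no source pixels to enumerate")
    vals = current.values[land]
    # snap to the increment lattice to deduplicate float representations
    keys = np.unique(np.round(vals / params.increment_step).astype(np.int64))
    return keys * params.increment_step
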