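"""Exposure metrics along least-cost climate trajectories.

For every land source pixel this module routes a trajectory to its
least-accumulated-cost future analogue and reports:

* ED — straight-line distance (km) to the nearest analogue;
* MED — length (km) of the least-exposure trajectory (>= ED);
* velocity_ED, velocity_MED — the two distances divided by the elapsed
  time between periods (km/yr);
* MCE — minimum cumulative exposure (°C), the penalty-scaled tally of
  dissimilarity met along the trajectory:
  MCE = (sum_i cost_i * l_i  -  MED) / p,
  zero exactly when the path never leaves analogue climate;
* the MED/ED ratio and per-pixel flags.

Forward mode (exposure) routes current-climate sources to future
analogues; reverse mode (accessibility) swaps the roles and reverses the
interpolated series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from .cost import build_final_cost, enumerate_increments
from .grids import MethodParams, TemperatureGrid
from .interpolate import InterpolatedSeries, interpolate_series
from .routing import (Trajectory, build_graph, dijkstra_batch, extract_path,
                      nearest_euclidean, select_destination)


def velocity_from_distance(distance_km, elapsed_time_yr: float):
    """Climate velocity (km/yr) implied by a displacement distance."""
    if elapsed_time_yr <= 0:
        raise ValueError("elapsed time must be positive")
    d = np.asarray(distance_km, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("distances must be non-negative")
    out = d / elapsed_time_yr
    return float(out) if np.ndim(distance_km) == 0 else out


def compute_mce(trajectory: Trajectory, params: MethodParams | None = None) -> float:
    """Minimum cumulative exposure (°C) of a routed trajectory.

    Computed as ``sum((cost_i - 1) * l_i) / p`` from the per-pixel costs and
    traversal lengths, which equals ``(accumulated_cost - MED) / p`` under
    the edge-weight accounting and is exactly zero for all-analogue paths.
    """
    params = params or MethodParams()
    excess = (trajectory.costs - 1.0) * trajectory.lengths
    return float(excess.sum()) / params.penalty


@dataclass
class ExposureResult:
    """Per-pixel exposure layers for one direction of analysis."""

    direction: str
    params: MethodParams
    pixel_size: float
    ed: np.ndarray
    med: np.ndarray
    velocity_ed: np.ndarray
    velocity_med: np.ndarray
    mce: np.ndarray
    ratio: np.ndarray
    dest_row: np.ndarray
    dest_col: np.ndarray
    source_mask: np.ndarray          # pixels that were routed as sources
    no_analogue: np.ndarray
    island_excluded: np.ndarray
    is_water: np.ndarray
    trajectories: dict = field(default_factory=dict)

    @property
    def valid_mask(self) -> np.ndarray:
        """Sources with metrics, excluding flagged pixels."""
        return (self.source_mask & ~self.no_analogue & ~self.island_excluded
                & np.isfinite(self.med))

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per source pixel, all metrics and flags."""
        rr, cc = np.nonzero(self.source_mask)
        return pd.DataFrame({
            "row": rr, "col": cc,
            "ed_km": self.ed[rr, cc], "med_km": self.med[rr, cc],
            "velocity_ed": self.velocity_ed[rr, cc],
            "velocity_med": self.velocity_med[rr, cc],
            "mce": self.mce[rr, cc], "ratio_med_ed": self.ratio[rr, cc],
            "dest_row": self.dest_row[rr, cc], "dest_col": self.dest_col[rr, cc],
            "no_analogue": self.no_analogue[rr, cc],
            "island_excluded": self.island_excluded[rr, cc],
        })

    def layers(self) -> dict[str, np.ndarray]:
        return {"ed": self.ed, "med": self.med, "velocity_ed": self.velocity_ed,
                "velocity_med": self.velocity_med, "mce": self.mce,
                "ratio_med_ed": self.ratio}


def _empty_like(shape, fill=np.nan):
    return np.full(shape, fill, dtype=float)


def _run_direction(source_grid: TemperatureGrid, analogue_grid: TemperatureGrid,
                   series: InterpolatedSeries, params: MethodParams,
                   direction: str, store_trajectories: bool) -> ExposureResult:
    shape = source_grid.shape
    ncol = shape[1]
    lattice = np.full(shape, np.iinfo(np.int64).min, dtype=np.int64)
    land = source_grid.land_mask
    lattice[land] = np.round(
        source_grid.values[land] / params.increment_step).astype(np.int64)

    ed = _empty_like(shape)
    med = _empty_like(shape)
    mce = _empty_like(shape)
    dest_row = np.full(shape, -1, dtype=np.int32)
    dest_col = np.full(shape, -1, dtype=np.int32)
    no_analogue = np.zeros(shape, dtype=bool)
    trajectories: dict = {}

    analogue_land = analogue_grid.land_mask
    nodata_union = source_grid.nodata_mask | analogue_grid.nodata_mask

    for T in enumerate_increments(source_grid, params):
        key = int(round(T / params.increment_step))
        src_mask = lattice == key
        if not src_mask.any():
            continue
        ana_mask = analogue_land & (
            np.abs(analogue_grid.values - T) <= params.half_width + 1e-9)
        sources = np.flatnonzero(src_mask.ravel())
        if not ana_mask.any():
            no_analogue[src_mask] = True
            continue
        surface = build_final_cost(T, series, water_mask=source_grid.water_mask,
                                   params=params, nodata_mask=nodata_union)
        graph = build_graph(surface, source_grid.pixel_size, params.neighbourhood)
        acc, pred = dijkstra_batch(graph, sources)
        for k, s in enumerate(sources):
            src = (s // ncol, s % ncol)
            acc2d = acc[k].reshape(shape)
            dest = select_destination(acc2d, ana_mask, src)
            ed_dest, ed_km = nearest_euclidean(src, ana_mask, source_grid.pixel_size)
            if dest is None or ed_dest is None:
                no_analogue[src] = True
                continue
            traj = extract_path(pred[k], src, dest, surface,
                                source_grid.pixel_size,
                                acc_at_destination=acc2d[dest])
            traj.ed = ed_km
            ed[src] = ed_km
            med[src] = traj.med
            mce[src] = compute_mce(traj, params)
            dest_row[src], dest_col[src] = dest
            if store_trajectories:
                trajectories[src] = traj

    velocity_ed = ed / params.elapsed_time
    velocity_med = med / params.elapsed_time
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((ed == 0) & (med == 0), 1.0, med / ed)
    ratio[(ed == 0) & (med > 0)] = np.nan

    result = ExposureResult(
        direction=direction, params=params, pixel_size=source_grid.pixel_size,
        ed=ed, med=med, velocity_ed=velocity_ed, velocity_med=velocity_med,
        mce=mce, ratio=ratio, dest_row=dest_row, dest_col=dest_col,
        source_mask=land.copy(), no_analogue=no_analogue,
        island_excluded=np.zeros(shape, dtype=bool),
        is_water=source_grid.water_mask.copy(), trajectories=trajectories)

    result.island_excluded = _classify.exclude_islands(
        land, dest_row, dest_col, land,
        min_island_area=params.min_island_area)
    return result


def run_forward(current: TemperatureGrid, future: TemperatureGrid,
                params: MethodParams | None = None,
                store_trajectories: bool = True) -> ExposureResult:
    """Forward (exposure) analysis: current sources to future analogues.

    For every land pixel of the current grid, builds the composite cost
    surface of its 0.1 °C increment, routes the least-exposure trajectory to
    the cheapest future analogue, and fills all metric layers.  Pixels with
    no analogue anywhere, and island sources/destinations, are flagged
    rather than failing the run.
    """
    params = params or MethodParams()
    current.check_coregistered(future)
    series = interpolate_series(current, future, params.n_steps)
    return _run_direction(current, future, series, params, "forward",
                          store_trajectories)


def run_reverse(current: TemperatureGrid, future: TemperatureGrid,
                params: MethodParams | None = None,
                store_trajectories: bool = True) -> ExposureResult:
    """Reverse (accessibility) analysis: future sources to current analogues.

    Measures how climatically accessible each site is to colonisation: the
    roles of the grids are swapped and the interpolated series reversed
    (future to current); the same cost and routing machinery applies.
    """
    params = params or MethodParams()
    current.check_coregistered(future)
    series = interpolate_series(current, future, params.n_steps).reversed()
    return _run_direction(future, current, series, params, "reverse",
                          store_trajectories)


def path_count_raster(result: ExposureResult) -> np.ndarray:
    """How many stored trajectories traverse each pixel (int32 layer).

    A quick density view of where least-exposure routes concentrate, e.g.
    corridors around water or through mountain passes.
    """
    counts = np.zeros(result.ed.shape, dtype=np.int32)
    for traj in result.trajectories.values():
        counts[traj.path[:, 0], traj.path[:, 1]] += 1
    return counts


def trajectories_to_geojson(result: ExposureResult) -> dict:
    """Trajectories as a GeoJSON FeatureCollection of LineStrings.

    Coordinates are grid-projected pixel centres (km from the grid origin,
    x east, y north-negative by row); properties carry MED, ED, MCE and
    accumulated cost per source.
    """
    feats = []
    px = result.pixel_size
    for (r, c), traj in sorted(result.trajectories.items()):
        coords = [[(cc + 0.5) * px, -(rr + 0.5) * px] for rr, cc in traj.path]
        if len(coords) == 1:
            coords = coords * 2
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString", "coordinates": coords},
            "properties": {"row": int(r), "col": int(c),
                           "med_km": traj.med, "ed_km": traj.ed,
                           "mce": compute_mce(traj, result.params),
                           "accumulated_cost": traj.accumulated_cost},
        })
    return {"type": "FeatureCollection", "features": feats}
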