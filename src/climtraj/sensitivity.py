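"""Sensitivity of velocity and MCE to resolution, bin width and penalty.

Mirrors the design of the method's sensitivity analysis: rerun the full
pipeline over a grid of (resolution, analogue bin width, dissimilarity
penalty) combinations and summarise each run by the geometric mean and the
5th/50th/95th percentiles of velocity_MED, velocity_ED, their ratio and
MCE.  Resolution is varied by block-mean aggregation of the input pair.

Geometric means are taken over strictly positive values; zeros are excluded
and their count reported alongside (``n_zero_*`` columns).  MCE percentiles
are reported over the MCE > 0 subset together with the MCE = 0 fraction.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .grids import MethodParams, TemperatureGrid, round_to_tenth
from .metrics import ExposureResult, run_forward


def coarsen(grid: TemperatureGrid, factor: int, stat: str = "mean") -> TemperatureGrid:
    """Block-aggregate a grid by an integer factor (mean statistic).

    Pixel size scales by ``factor``; partial edge blocks are dropped.  The
    aggregated temperatures are re-rounded to 0.1 °C (the ingest contract).
    A block is water when at least half its pixels are water, and nodata
    when every pixel is nodata.
    """
    if stat != "mean":
        raise ValueError("only mean aggregation is supported")
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    nrow, ncol = grid.shape
    nr, nc = nrow // factor, ncol // factor
    if nr == 0 or nc == 0:
        raise ValueError(f"factor {factor} larger than grid {grid.shape}")

    def blocks(a):
        return a[:nr * factor, :nc * factor].reshape(nr, factor, nc, factor)

    vals = np.where(grid.nodata_mask, np.nan, grid.values)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(blocks(vals), axis=(1, 3))
    nodata = ~np.isfinite(mean)
    water = blocks(grid.water_mask).mean(axis=(1, 3)) >= 0.5
    out = round_to_tenth(mean)
    out[nodata] = np.nan
    return TemperatureGrid(values=out, pixel_size=grid.pixel_size * factor,
                           origin=grid.origin, nodata_mask=nodata,
                           water_mask=water, name=grid.name)


def _gmean_pos(x):
    x = x[np.isfinite(x)]
    pos = x[x > 0]
    g = float(stats.gmean(pos)) if pos.size else np.nan
    return g, int((x == 0).sum())


def _pcts(x, qs=(5, 50, 95)):
    x = x[np.isfinite(x)]
    if x.size == 0:
        return [np.nan] * len(qs)
    return list(np.percentile(x, qs))


def summarize(result: ExposureResult) -> dict:
    """Geometric mean + 5/50/95th percentile summary of one run."""
    valid = result.valid_mask
    out = {}
    for name, layer in (("velocity_med", result.velocity_med),
                        ("velocity_ed", result.velocity_ed),
                        ("ratio", result.ratio)):
        x = layer[valid]
        g, nz = _gmean_pos(x)
        p5, p50, p95 = _pcts(x)
        out.update({f"gmean_{name}": g, f"n_zero_{name}": nz,
                    f"p5_{name}": p5, f"p50_{name}": p50, f"p95_{name}": p95})
    m = result.mce[valid]
    m = m[np.isfinite(m)]
    pos = m[m > 0]
    g, nz = _gmean_pos(m)
    p5, p50, p95 = _pcts(pos)
    out.update({"gmean_mce": g, "n_zero_mce": nz,
                "frac_mce_zero": float((m == 0).mean()) if m.size else np.nan,
                "p5_mce": p5, "p50_mce": p50, "p95_mce": p95,
                "n_valid": int(valid.sum())})
    return out


def sweep(current: TemperatureGrid, future: TemperatureGrid,
          resolutions=(1,), bin_widths=(0.5,), penalties=(2.0,),
          params: MethodParams | None = None) -> pd.DataFrame:
    """Full-pipeline sweep over resolution factors, bin widths and penalties.

    ``bin_widths`` are full analogue bin widths in °C (half_width is half of
    each); ``resolutions`` are integer coarsening factors applied to both
    grids.  Returns one summary row per combination; deterministic for
    deterministic fixtures.
    """
    params = params or MethodParams()
    rows = []
    for factor in resolutions:
        cur = coarsen(current, factor) if factor > 1 else current
        fut = coarsen(future, factor) if factor > 1 else future
        for bw in bin_widths:
            for p in penalties:
                pp = params.with_(half_width=bw / 2.0, penalty=p)
                res = run_forward(cur, fut, pp, store_trajectories=False)
                row = {"resolution_km": cur.pixel_size, "coarsen_factor": factor,
                       "bin_width": bw, "penalty": p}
                row.update(summarize(res))
                rows.append(row)
    return pd.DataFrame(rows)
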