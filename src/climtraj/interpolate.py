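"""Temporal interpolation of temperature grids.

Trajectories are allowed to follow the climate as it warms: instead of
costing dissimilarity against a single time slice, the cost model takes the
minimum dissimilarity over a series of temperature grids linearly
interpolated between the current and future periods.  This module builds
that series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import TemperatureGrid


@dataclass
class InterpolatedSeries:
    """Ordered stack of temperature fields from the current to the future
    period.

    ``grids[0]`` is the current field and ``grids[-1]`` the future field,
    exactly; intermediate fields are linear blends and are deliberately not
    re-rounded to 0.1 °C (only ingested endpoint grids are rounded; cost
    banding handles arbitrary precision).
    """

    grids: np.ndarray            # (n_steps, nrow, ncol)
    years: np.ndarray            # nominal year of each step

    def __len__(self) -> int:
        return self.grids.shape[0]

    def reversed(self) -> "InterpolatedSeries":
        """Future-to-current ordering, used by the reverse (accessibility)
        analysis."""
        return InterpolatedSeries(grids=self.grids[::-1], years=self.years[::-1])


def interpolate_series(current: TemperatureGrid, future: TemperatureGrid,
                       n_steps: int = 31, start_year: float = 1995.0,
                       end_year: float = 2085.0) -> InterpolatedSeries:
    """Linearly interpolate ``n_steps`` temperature grids between the pair.

    Step ``k`` equals ``current + (k / (n_steps-1)) * (future - current)``;
    with the default 31 steps over a 90-year interval the grids fall on
    three-year increments.  Per-pixel values are monotone along the series,
    increasing where the future is warmer and decreasing where it cools.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    current.check_coregistered(future)
    frac = np.linspace(0.0, 1.0, n_steps)
    cur = current.values[None, :, :]
    fut = future.values[None, :, :]
    grids = cur + frac[:, None, None] * (fut - cur)
    # guarantee exact endpoint fidelity against floating blends
    grids[0] = current.values
    grids[-1] = future.values
    years = np.linspace(start_year, end_year, n_steps)
    return InterpolatedSeries(grids=grids, years=years)
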