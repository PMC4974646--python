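"""Synthetic temperature landscapes with analytically known ground truth.

Each generator returns a co-registered (current, future) pair of
:class:`~climtraj.grids.TemperatureGrid` plus a dictionary of ground-truth
quantities computable in closed form from the construction, so that every
pipeline stage can be tested end to end without external climate data.

Conventions: row 0 is the northern (cool, poleward) edge and temperature
increases southward unless stated otherwise; warming is spatially uniform.
Noise is off by default so worked-example values are exact; when requested
it is deterministic under the given seed.
"""

from __future__ import annotations

import numpy as np

from .grids import TemperatureGrid, round_to_tenth


def _pair(cur_values, fut_values, pixel_size, water_mask=None):
    cur = TemperatureGrid(values=round_to_tenth(cur_values), pixel_size=pixel_size,
                          water_mask=water_mask, name="current")
    fut = TemperatureGrid(values=round_to_tenth(fut_values), pixel_size=pixel_size,
                          water_mask=None if water_mask is None else water_mask.copy(),
                          name="future")
    return cur, fut


def make_flat_gradient(shape=(50, 50), pixel_size=5.0, gradient=0.05,
                       warming=1.0, base_temp=5.0, noise_sd=0.0, seed=0):
    """Flat terrain with a pure latitudinal gradient under uniform warming.

    Temperature increases southward (toward higher row index) by ``gradient``
    °C per pixel; the future grid is ``current + warming``.  Every pixel's
    future analogue therefore sits ``warming / gradient`` pixels poleward,
    the climate trajectory is a straight poleward line through pixels that
    warm through the source temperature, and MCE is identically zero.

    Returns ``(current, future, truth)`` where ``truth`` holds the analytic
    displacement (pixels and km) and the implied straight-line velocity.
    """
    if gradient == 0:
        raise ValueError("gradient must be nonzero: a flat field has no "
                         "analogue direction")
    nrow, ncol = shape
    rows = np.arange(nrow, dtype=float)[:, None]
    cur = base_temp + gradient * rows * np.ones((1, ncol))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cur = cur + rng.normal(0.0, noise_sd, size=(nrow, ncol))
    fut = cur + warming
    displacement_px = warming / gradient
    current, future = _pair(cur, fut, pixel_size)
    # Nearest-analogue displacement on the rounded lattice: the analogue bin
    # (± half 0.5 °C) admits pixels closer than the exact-match displacement,
    # so ED/MED run to the near bin edge.  Scan one column (noise-free case).
    nearest_px = None
    if noise_sd == 0:
        r0 = nrow // 2
        col_cur = current.values[:, 0]
        col_fut = future.values[:, 0]
        hits = np.abs(col_fut - col_cur[r0]) <= 0.25 + 1e-9
        if hits.any():
            nearest_px = int(np.min(np.abs(np.flatnonzero(hits) - r0)))
    truth = {
        "displacement_pixels": displacement_px,
        "displacement_km": displacement_px * pixel_size,
        "reference_row": nrow // 2,
        "nearest_analogue_displacement_pixels": nearest_px,
        "nearest_analogue_displacement_km":
            None if nearest_px is None else nearest_px * pixel_size,
        "expected_mce": 0.0,
    }
    return current, future, truth


def make_ridge_valley(shape=(21, 9), pixel_size=5.0, ridge_height_profile=None,
                      lapse_rate=1.0, base_gradient=0.0, base_temp=5.5,
                      warming=1.0, valley_width=1, valley_delta=0.5,
                      source_rows=None):
    """Two ridges separated by a warm valley: the mountain-top scenario.

    Temperature is ``base_temp + base_gradient*row - lapse_rate*elevation``
    with elevation given per row by ``ridge_height_profile`` (in elevation
    units; with the default ``lapse_rate`` of 1 °C per unit, profile values
    read directly as °C of cooling).  The default profile builds, from north
    to south: a source ridge cooled by ``valley_delta``, a valley of
    ``valley_width`` rows at ``base_temp`` (warmer than the ridge by
    ``valley_delta``), and a destination ridge cooled by
    ``valley_delta + warming`` so that under uniform ``warming`` its future
    temperature exactly matches the source ridge's current temperature.

    With ``valley_delta`` = 0.5 °C and the default analogue half-width of
    0.25 °C, every valley pixel sits in the second cost band (cost 2) at all
    interpolation times, so the least-exposure trajectory from any source
    ridge pixel accrues exactly ``valley_width * pixel_size`` km of cost-2
    traversal: MCE = ``valley_width * pixel_size * (band-1) / p``.

    Returns ``(current, future, truth)``; ``truth`` includes the expected
    MCE at the stated penalty for source-ridge pixels.
    """
    nrow, ncol = shape
    if ridge_height_profile is None:
        n_a = (nrow - valley_width) // 2
        n_b = nrow - valley_width - n_a
        profile = np.concatenate([
            np.full(n_a, valley_delta),            # source ridge (cooler than valley)
            np.zeros(valley_width),                # valley floor (warm)
            np.full(n_b, valley_delta + warming),  # destination ridge (cooler still)
        ])
        source_rows = np.arange(n_a) if source_rows is None else source_rows
    else:
        profile = np.asarray(ridge_height_profile, dtype=float)
        if profile.size != nrow:
            raise ValueError("ridge_height_profile length must equal shape[0]")
    rows = np.arange(nrow, dtype=float)
    temps = base_temp + base_gradient * rows - lapse_rate * profile
    valley_temp = temps.max()
    if valley_temp <= temps[0]:
        import warnings
        warnings.warn("degenerate profile: valley is not warmer than the ridge",
                      stacklevel=2)
    cur = np.repeat(temps[:, None], ncol, axis=1)
    fut = cur + warming
    # Cost band of the valley crossing at default parameters (half_width 0.25):
    # dissimilarity valley_delta -> band 1 + ceil((delta - hw)/(2*hw)).
    truth = {
        "source_rows": None if source_rows is None else np.asarray(source_rows),
        "valley_width": valley_width,
        "valley_delta": valley_delta,
        "crossing_km": valley_width * pixel_size,
        "expected_mce_at_defaults": None,
    }
    hw, p = 0.25, 2.0
    if valley_delta > hw:
        band = 1 + int(np.ceil((valley_delta - hw) / (2 * hw) - 1e-9))
        truth["expected_mce_at_defaults"] = valley_width * pixel_size * (band - 1) / p
    else:
        truth["expected_mce_at_defaults"] = 0.0
    current, future = _pair(cur, fut, pixel_size)
    return current, future, truth


def make_peninsula(shape=(24, 15), pixel_size=5.0, gradient=0.3, warming=0.6,
                   water_frame=3, peninsula_width=3, peninsula_length=10,
                   highland_rows=3, include_island=True, all_land=False):
    """North-pointing peninsula surrounded by water on three sides.

    A latitudinal gradient (cool north) covers the grid; the northern part
    is open water except for a land tongue of ``peninsula_width`` columns
    reaching ``peninsula_length`` rows north of the southern mainland.  The
    only climate analogues for peninsula pixels live on a cold highland
    block placed on the southern mainland (its current temperature is set to
    the tip temperature minus ``warming``), so trajectories from the tip
    must run south through rows warmer than the source band — accruing
    MCE > 0 — or cross water at the water cost.  With ``all_land=True`` the
    water is replaced by land continuing the gradient; the default warming
    keeps the poleward displacement (``warming / gradient`` pixels) inside
    the former water frame, so the control scenario recovers a monotone
    poleward route with zero exposure.

    ``include_island`` adds a one-pixel island in the northwestern water,
    exercising the island-exclusion policy downstream.

    Returns ``(current, future, truth)``.
    """
    nrow, ncol = shape
    rows = np.arange(nrow, dtype=float)[:, None]
    cur = gradient * rows * np.ones((1, ncol))

    mainland_top = water_frame + peninsula_length   # first all-land row
    pc0 = (ncol - peninsula_width) // 2
    pc1 = pc0 + peninsula_width
    tip_row = water_frame

    water = np.zeros((nrow, ncol), dtype=bool)
    if not all_land:
        water[:mainland_top, :] = True
        water[tip_row:mainland_top, pc0:pc1] = False   # the peninsula tongue
        if include_island:
            water[water_frame // 2, 0] = False          # 1-pixel island, NW corner

    # Cold highland on the southern mainland: the tip's only land analogues.
    tip_temp = gradient * tip_row
    hr0 = nrow - highland_rows
    cur[hr0:, :] = tip_temp - warming
    fut = cur + warming

    truth = {
        "tip_row": tip_row,
        "tip_cols": (pc0, pc1),
        "mainland_top_row": mainland_top,
        "highland_rows": (hr0, nrow),
        "island_pixel": (water_frame // 2, 0) if (include_island and not all_land) else None,
        "tip_temp": tip_temp,
        "displacement_pixels": warming / gradient,
    }
    current, future = _pair(cur, fut, pixel_size, water_mask=water)
    return current, future, truth
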