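"""Raster data model and GeoTIFF input/output.

A :class:`TemperatureGrid` holds a single-band mean-annual-temperature raster
(°C) on an equal-area projected grid with square pixels, together with its
nodata and water masks and minimal georeferencing (origin and pixel size).
All downstream stages — temporal interpolation, cost surfaces, least-cost
routing, exposure metrics — operate on co-registered pairs of these grids.

GeoTIFF files are read and written with :mod:`tifffile`, carrying the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and
the GDAL nodata convention, so outputs open in ordinary GIS software.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids / values
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
_RASTER_PIXEL_IS_AREA = 1

DEFAULT_NODATA = -9999.0


def round_to_tenth(values):
    """Round temperatures to the nearest 0.1 °C, halves away from zero.

    Idempotent: re-rounding an already rounded grid is a no-op.  A small
    epsilon guards against binary representations of decimal halves
    (e.g. ``5.05`` stored as ``5.049999...``).
    """
    v = np.asarray(values, dtype=float)
    return np.sign(v) * np.floor(np.abs(v) * 10.0 + 0.5 + 1e-9) / 10.0


def elapsed_time_from_periods(current_period: str, future_period: str) -> float:
    """Elapsed years between the midpoints of two ``"YYYY-YYYY"`` periods.

    ``("1981-2010", "2071-2100")`` gives 90 years, the interval between the
    1995.5 and 2085.5 period midpoints.
    """

    def midpoint(period: str) -> float:
        try:
            a, b = (int(p) for p in period.split("-"))
        except ValueError as exc:
            raise ValueError(f"period must look like 'YYYY-YYYY', got {period!r}") from exc
        return (a + b + 1) / 2.0

    dt = midpoint(future_period) - midpoint(current_period)
    if dt <= 0:
        raise ValueError("future period must postdate the current period")
    return dt


@dataclass
class MethodParams:
    """Tunable parameters of the velocity/MCE method.

    Attributes
    ----------
    half_width:
        Half the analogue bin width in °C.  A pixel is a climate analogue of
        a temperature increment ``T`` when its temperature lies within
        ``T ± half_width``.  Default 0.25 °C (bin width 0.5 °C).
    increment_step:
        Spacing of the isotherm increments in °C (the ingest rounding
        resolution).  Default 0.1 °C.
    penalty:
        Dissimilarity penalty ``p`` in dimensionless cost units per °C used
        to convert accumulated excess cost back to °C of exposure.  Default
        2 (one cost unit per 0.5 °C band).
    water_cost:
        Cost assigned to open-water pixels in the final cost surfaces;
        heavily penalises but does not forbid water crossings.  Default 5000.
    n_steps:
        Number of linearly interpolated temperature grids between the
        current and future period (inclusive of both).  Default 31.
    elapsed_time:
        Years between the current and future periods; divides trajectory
        lengths into velocities.  Default 90.
    neighbourhood:
        Grid-graph connectivity for routing, 4 or 8.  Default 8.
    cost_form:
        ``"integer"`` for the banded integer cost (canonical) or
        ``"continuous"`` for ``penalty * |ΔT| + 1``.
    min_island_area:
        Land components (8-connected) with fewer pixels than this are
        treated as islands.  ``None`` means every component except the
        largest is an island.
    """

    half_width: float = 0.25
    increment_step: float = 0.1
    penalty: float = 2.0
    water_cost: float = 5000.0
    n_steps: int = 31
    elapsed_time: float = 90.0
    neighbourhood: int = 8
    cost_form: str = "integer"
    min_island_area: int | None = None

    def __post_init__(self):
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")
        if self.increment_step <= 0:
            raise ValueError("increment_step must be > 0")
        if self.penalty <= 0:
            raise ValueError("penalty P must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.elapsed_time <= 0:
            raise ValueError("elapsed_time must be > 0")
        if self.neighbourhood not in (4, 8):
            raise ValueError("neighbourhood must be 4 or 8")
        if self.cost_form not in ("integer", "continuous"):
            raise ValueError("cost_form must be 'integer' or 'continuous'")
        if self.water_cost <= 1:
            raise ValueError("water_cost must exceed achievable land costs")

    def with_(self, **kwargs) -> "MethodParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class TemperatureGrid:
    """A single-band temperature raster with masks and georeferencing.

    ``values`` are mean annual temperatures in °C, rounded to 0.1 °C on
    ingest so that analogue-bin membership is reproducible.  ``pixel_size``
    is the square pixel edge in km on an equal-area projection; planar
    distances in km follow directly from pixel offsets.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = None
    water_mask: np.ndarray = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 (km)")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.water_mask is None:
            self.water_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.water_mask = np.asarray(self.water_mask, dtype=bool)
        for m in (self.nodata_mask, self.water_mask):
            if m.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def land_mask(self) -> np.ndarray:
        """Valid land pixels: finite, not nodata, not water."""
        return ~self.nodata_mask & ~self.water_mask

    def check_coregistered(self, other: "TemperatureGrid") -> None:
        """Raise ``ValueError`` unless the two grids share shape, pixel size
        and origin (the co-registration contract for current/future pairs)."""
        if self.shape != other.shape:
            raise ValueError(
                f"co-registration error: shapes differ {self.shape} vs {other.shape}"
            )
        if not np.isclose(self.pixel_size, other.pixel_size):
            raise ValueError(
                "co-registration error: pixel sizes differ "
                f"{self.pixel_size} vs {other.pixel_size} km"
            )
        if not np.allclose(self.origin, other.origin):
            raise ValueError(
                f"co-registration error: origins differ {self.origin} vs {other.origin}"
            )

    def rounded(self) -> "TemperatureGrid":
        """Copy with values rounded to 0.1 °C (ingest normalisation)."""
        out = replace(self)
        out.values = round_to_tenth(self.values)
        out.values[self.nodata_mask] = np.nan
        return out


def _geotiff_extratags(pixel_size_km: float, origin: tuple[float, float], nodata):
    scale_m = pixel_size_km * 1000.0
    geokeys = [
        1, 1, 0, 2,
        _GT_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED,
        _GT_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA,
    ]
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (scale_m, scale_m, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0), True),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), tuple(geokeys), True),
    ]
    if nodata is not None:
        s = repr(float(nodata)) if not float(nodata).is_integer() else str(int(nodata))
        tags.append((_TAG_GDAL_NODATA, "s", len(s) + 1, s, True))
    return tags


def write_raster(values, path, *, like: TemperatureGrid | None = None,
                 pixel_size: float | None = None, origin=(0.0, 0.0),
                 nodata=DEFAULT_NODATA, nodata_mask=None, dtype=None) -> None:
    """Write a 2D result layer as a single-band GeoTIFF.

    Float layers are written as float32, integer layers (class/flag rasters)
    as int32; nodata pixels are encoded with the declared nodata value and
    advertised through the GDAL nodata tag.  Round-trips are lossless.
    """
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError("write_raster expects a 2D layer")
    if like is not None:
        pixel_size = like.pixel_size
        origin = like.origin
        if nodata_mask is None:
            nodata_mask = like.nodata_mask
    if pixel_size is None:
        raise ValueError("pixel_size (km) required when no template grid is given")
    if dtype is None:
        dtype = np.int32 if np.issubdtype(arr.dtype, np.integer) else np.float32
    out = arr.astype(dtype)
    if nodata is not None:
        bad = ~np.isfinite(arr) if np.issubdtype(arr.dtype, np.floating) else \
            np.zeros(arr.shape, bool)
        if nodata_mask is not None:
            bad = bad | nodata_mask
        out = np.where(bad, np.array(nodata, dtype=dtype), out)
    tifffile.imwrite(
        path, out, extratags=_geotiff_extratags(pixel_size, origin, nodata))


def _read_page(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        tags = {code: page.tags[code].value
                for code in (_TAG_MODEL_PIXEL_SCALE, _TAG_MODEL_TIEPOINT,
                             _TAG_GEO_KEY_DIRECTORY, _TAG_GDAL_NODATA)
                if code in page.tags}
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {arr.shape}")
    return arr, tags


def _georef_from_tags(path, tags):
    if _TAG_GEO_KEY_DIRECTORY in tags:
        keys = tags[_TAG_GEO_KEY_DIRECTORY]
        for i in range(4, len(keys) - 3, 4):
            if keys[i] == _GT_MODEL_TYPE and keys[i + 3] == _MODEL_TYPE_GEOGRAPHIC:
                raise ValueError(
                    f"{path}: grid is in geographic (degree) coordinates; this method "
                    "requires an equal-area projected grid with pixel size in km")
    if _TAG_MODEL_PIXEL_SCALE not in tags:
        raise ValueError(
            f"{path}: no ModelPixelScale tag; an equal-area projected GeoTIFF "
            "with square pixels (km units) is required")
    sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
    if not np.isclose(sx, sy):
        raise ValueError(
            f"{path}: non-square pixels ({sx} x {sy} m); square pixels on an "
            "equal-area projection (km units) are required")
    origin = (0.0, 0.0)
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT]
        origin = (float(tp[3]), float(tp[4]))
    return sx / 1000.0, origin


def read_temperature_raster(path, water_path=None, *, name="") -> TemperatureGrid:
    """Read a temperature GeoTIFF (and optional co-registered water raster).

    Values are rounded to the nearest 0.1 °C on ingest; nodata pixels (the
    file's declared nodata value, plus NaNs) are masked out of all later
    routing and analogue searches.
    """
    arr, tags = _read_page(path)
    pixel_size, origin = _georef_from_tags(path, tags)
    values = arr.astype(float)
    nodata_mask = ~np.isfinite(values)
    if _TAG_GDAL_NODATA in tags:
        nd = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        nodata_mask |= np.isclose(values, nd)
    values = round_to_tenth(values)
    values[nodata_mask] = np.nan

    water_mask = None
    if water_path is not None:
        warr, wtags = _read_page(water_path)
        wps, worigin = _georef_from_tags(water_path, wtags)
        if warr.shape != arr.shape or not np.isclose(wps, pixel_size) \
                or not np.allclose(worigin, origin):
            raise ValueError(
                f"co-registration error: water raster {water_path} does not match "
                f"{path} in shape, pixel size or origin")
        wvals = warr.astype(float)
        if _TAG_GDAL_NODATA in wtags:
            nd = float(str(wtags[_TAG_GDAL_NODATA]).strip("\x00 "))
            wvals[np.isclose(wvals, nd)] = 0.0
        water_mask = wvals > 0

    return TemperatureGrid(values=values, pixel_size=pixel_size, origin=origin,
                           nodata_mask=nodata_mask, water_mask=water_mask,
                           name=name or os.path.basename(path))


def write_grid(grid: TemperatureGrid, path, water_path=None) -> None:
    """Write a :class:`TemperatureGrid` (and optionally its water mask)."""
    write_raster(grid.values, path, like=grid)
    if water_path is not None:
        write_raster(grid.water_mask.astype(np.int32), water_path,
                     pixel_size=grid.pixel_size, origin=grid.origin, nodata=None)
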