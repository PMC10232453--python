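"""Vegetation condition indices and drought classification.

The Vegetation Condition Index (VCI) rescales NDVI between its historical
extremes so 0 is the worst greenness ever observed at a pixel and 100 the
best; the Thermal Condition Index (TCI) rescales land surface temperature
inversely, so the hottest year maps to 0. The Vegetation Health Index is
their convex combination

    VHI = a * VCI + (1 - a) * TCI,   a in [0, 1]

with the conventional equal-weight baseline a = 0.5. Values of VHI at or
below 40 indicate vegetation drought; the seven-class rating scale runs
from Extremely dry [0, 10] to Excellent (60, 100].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import RasterCube

__all__ = [
    "DroughtClass", "CLASS_BOUNDS", "compute_vci", "compute_tci",
    "compute_vhi", "classify", "classify_cube", "drought_mask",
    "DEFAULT_THRESHOLD", "BASELINE_WEIGHT",
]

#: Drought threshold on the VHI rating scale.
DEFAULT_THRESHOLD = 40.0
#: Equal-contribution weight of the original VHI.
BASELINE_WEIGHT = 0.5


class DroughtClass(IntEnum):
    """Seven-class vegetation drought rating; codes 1..7 are the GeoTIFF coding."""

    EXTREMELY_DRY = 1   # [0, 10]
    SEVERELY_DRY = 2    # (10, 20]
    MODERATELY_DRY = 3  # (20, 30]
    MILD_DRY = 4        # (30, 40]
    NORMAL = 5          # (40, 50]
    GOOD = 6            # (50, 60]
    EXCELLENT = 7       # (60, 100]


#: Upper bounds of each class interval; the first interval is closed at 0,
#: every subsequent one is left-open. Together they partition [0, 100].
CLASS_BOUNDS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 100.0)


def classify(vhi_value: float) -> DroughtClass:
    """Map a VHI value in [0, 100] to its drought class."""
    v = float(vhi_value)
    if not (0.0 <= v <= 100.0):
        raise ValueError(f"VHI value {v} outside [0, 100]")
    for cls, upper in zip(DroughtClass, CLASS_BOUNDS):
        if v <= upper:
            return cls
    raise AssertionError("unreachable: bounds cover [0, 100]")


def classify_cube(vhi: RasterCube) -> RasterCube:
    """Integer-coded class map (1=Extremely dry .. 7=Excellent); invalid -> 0."""
    vals = vhi.values
    if np.any((vals[vhi.valid] < 0) | (vals[vhi.valid] > 100)):
        raise ValueError("valid VHI values must lie in [0, 100]")
    codes = 1 + np.searchsorted(np.asarray(CLASS_BOUNDS[:-1]), vals, side="left")
    codes = np.where(vhi.valid, codes, 0).astype(float)
    return vhi.like(codes, valid=vhi.valid.copy())


def _minmax_scale(cube: RasterCube, invert: bool, scope: str) -> RasterCube:
    if cube.n_times == 0:
        raise ValueError("empty cube")
    if scope not in ("pixel", "global"):
        raise ValueError(f"unknown extrema scope {scope!r}")
    vals = cube.masked()
    with np.errstate(invalid="ignore"):
        if scope == "pixel":
            lo = np.nanmin(vals, axis=0, initial=np.inf, where=cube.valid)
            hi = np.nanmax(vals, axis=0, initial=-np.inf, where=cube.valid)
        else:
            lo = np.full(cube.grid.shape, np.nanmin(vals) if cube.valid.any() else np.inf)
            hi = np.full(cube.grid.shape, np.nanmax(vals) if cube.valid.any() else -np.inf)
    span = hi - lo
    ok = np.isfinite(span) & (span > 0)
    safe_span = np.where(ok, span, 1.0)
    if invert:
        scaled = (hi[None] - vals) / safe_span[None] * 100.0
    else:
        scaled = (vals - lo[None]) / safe_span[None] * 100.0
    valid = cube.valid & ok[None]
    scaled = np.where(valid, scaled, 0.0)
    return cube.like(scaled, valid=valid)


def compute_vci(ndvi: RasterCube, scope: str = "pixel") -> RasterCube:
    """VCI = (NDVI - NDVI_min) / (NDVI_max - NDVI_min) * 100.

    By default the extrema are each pixel's own min/max over its valid
    series, matching the operational multi-year-climatology construction of
    distributed VCI products; ``scope="global"`` uses one min/max over all
    pixels and periods instead. Pixels with a constant series (zero range)
    are invalid.
    """
    return _minmax_scale(ndvi, invert=False, scope=scope)


def compute_tci(lst: RasterCube, scope: str = "pixel") -> RasterCube:
    """TCI = (LST_max - LST) / (LST_max - LST_min) * 100 (hot -> 0, cool -> 100)."""
    return _minmax_scale(lst, invert=True, scope=scope)


def _as_weight_array(weights, shape) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full(shape, float(w))
    if w.shape != shape:
        raise ValueError(f"weight field shape {w.shape} does not match grid {shape}")
    finite = np.isfinite(w)
    if np.any((w[finite] < 0) | (w[finite] > 1)):
        raise ValueError("weights must lie in [0, 1]")
    return w


def compute_vhi(vci: RasterCube, tci: RasterCube, weights) -> RasterCube:
    """VHI = a * VCI + (1 - a) * TCI, with scalar or per-pixel weight a.

    Non-finite entries of a per-pixel weight field mark pixels with no
    usable weight; their outputs are invalid.
    """
    if not vci.grid.approx_equal(tci.grid):
        raise ValueError("VCI and TCI grids differ")
    if list(vci.times) != list(tci.times):
        raise ValueError("VCI and TCI time axes differ")
    w = _as_weight_array(weights, vci.grid.shape)
    w_ok = np.isfinite(w)
    safe_w = np.where(w_ok, w, 0.0)
    vhi = safe_w[None] * vci.values + (1.0 - safe_w[None]) * tci.values
    valid = vci.valid & tci.valid & w_ok[None]
    vhi = np.where(valid, vhi, 0.0)
    return vci.like(vhi, valid=valid)


def drought_mask(
    vhi: RasterCube,
    threshold: float = DEFAULT_THRESHOLD,
    boundary_inclusive: bool = True,
) -> RasterCube:
    """Boolean drought flags (1 = drought) per cell.

    A cell is in drought where VHI <= threshold (the rating scale puts 40
    itself in the Mild dry class); ``boundary_inclusive=False`` switches to
    a strict VHI < threshold reading. Invalid cells stay invalid.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must lie in (0, 100)")
    if boundary_inclusive:
        flags = vhi.values <= threshold
    else:
        flags = vhi.values < threshold
    flags = flags & vhi.valid
    return vhi.like(flags.astype(float), valid=vhi.valid.copy())
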