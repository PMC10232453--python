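"""Temporal aggregation and grid alignment.

Distributed vegetation-health products arrive as weekly composites on a
fine grid while reference drought indices arrive monthly on a coarse grid;
before calibration both must live on one grid and one time axis. Weekly or
monthly layers are averaged arithmetically into monthly/annual means, and
the coarse reference is transferred onto the fine grid by nearest-neighbor
lookup (no interpolation, so reference values are replicated, not blended).
"""

from __future__ import annotations

import numpy as np

from .core import GridSpec, RasterCube, TimeLabel, label_sort_key, week_to_month

__all__ = ["aggregate_time", "resample_nearest"]

_FINER: dict[str, tuple[str, ...]] = {
    "annual": ("weekly", "monthly"),
    "monthly": ("weekly",),
}


def _period_of(label: TimeLabel, freq: str, target: str) -> TimeLabel:
    if target == "annual":
        return label[0] if isinstance(label, tuple) else int(label)
    # target == "monthly": label is a (year, week) pair
    year, week = label  # type: ignore[misc]
    return (int(year), week_to_month(int(year), int(week)))


def aggregate_time(cube: RasterCube, target: str, min_count: int = 1) -> RasterCube:
    """Average a weekly/monthly cube into monthly or annual means.

    Each output cell is the arithmetic mean of the valid input cells in its
    period; it is invalid where fewer than ``min_count`` inputs are valid.
    Weeks straddling a month boundary belong to the month containing the
    week's start date.
    """
    if target not in ("monthly", "annual"):
        raise ValueError(f"unknown aggregation target {target!r}")
    if cube.freq not in _FINER[target]:
        raise ValueError(
            f"cannot aggregate {cube.freq} data to {target}: target must be coarser"
        )
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    periods = [_period_of(t, cube.freq, target) for t in cube.times]
    out_times = sorted(set(periods), key=label_sort_key)
    index = {p: i for i, p in enumerate(out_times)}

    shape = (len(out_times), cube.grid.n_rows, cube.grid.n_cols)
    sums = np.zeros(shape)
    counts = np.zeros(shape, dtype=int)
    for layer, mask, period in zip(cube.values, cube.valid, periods):
        i = index[period]
        sums[i] += np.where(mask, layer, 0.0)
        counts[i] += mask

    valid = counts >= min_count
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return RasterCube(cube.grid, out_times, means, valid, freq=target)


def _nearest_index(target_centers: np.ndarray, pixel_size: float,
                   n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest source index along one axis, plus an in-extent flag.

    ``target_centers`` are signed offsets from the source origin measured in
    the direction of increasing index. Ties (a target center equidistant
    between two source centers) resolve to the smaller index.
    """
    f = target_centers / pixel_size - 0.5  # fractional source index
    lo = np.floor(f)
    idx = np.where(f - lo <= 0.5, lo, lo + 1).astype(int)
    inside = (f >= -0.5) & (f <= n - 0.5)
    return np.clip(idx, 0, n - 1), inside


def resample_nearest(source: RasterCube, target_grid: GridSpec) -> RasterCube:
    """Transfer a cube onto ``target_grid`` by nearest-center lookup.

    Each target cell takes the value and validity of the source cell whose
    center is nearest its own center. Target cells whose centers fall
    outside the source extent (beyond half a source pixel past the edge)
    are invalid. The time axis is unchanged. Both grids must share a CRS;
    reprojection is out of scope.
    """
    if source.grid.crs_id != target_grid.crs_id:
        raise ValueError(
            f"CRS mismatch: source {source.grid.crs_id!r} vs target {target_grid.crs_id!r}"
        )
    sg = source.grid
    cols, cols_in = _nearest_index(
        target_grid.x_centers() - sg.origin_x, sg.pixel_size_x, sg.n_cols
    )
    # rows count downward from the northern origin
    rows, rows_in = _nearest_index(
        sg.origin_y - target_grid.y_centers(), sg.pixel_size_y, sg.n_rows
    )
    values = source.values[:, rows[:, None], cols[None, :]]
    valid = source.valid[:, rows[:, None], cols[None, :]]
    valid = valid & rows_in[:, None] & cols_in[None, :]
    values = np.where(valid, values, 0.0)
    return RasterCube(target_grid, list(source.times), values, valid, freq=source.freq)
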