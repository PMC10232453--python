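"""Core gridded-data containers.

A :class:`RasterCube` is the package's working representation of a gridded
index time series (NDVI, LST, VCI, TCI, VHI, or a reference drought index
such as sc-PDSI): a ``(time, row, col)`` array of values plus a boolean
validity mask, georeferenced by a :class:`GridSpec`.

Missing data are carried as the mask, never as a sentinel value; the
``-9999`` background convention of distributed index products exists only
at file boundaries (see :mod:`vhiopt.io`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["GridSpec", "RasterCube", "TimeLabel", "label_sort_key", "label_str"]

#: A time label: a plain year (annual data) or a ``(year, sub)`` pair where
#: ``sub`` is a 1-based month (monthly data) or week-of-year (weekly data).
TimeLabel = int | tuple[int, int]

_COORD_TOL = 1e-9  # absolute tolerance for map-coordinate equality


def label_sort_key(label: TimeLabel) -> tuple[int, int]:
    """Sort key placing annual labels and (year, sub) pairs on one axis."""
    if isinstance(label, tuple):
        return (int(label[0]), int(label[1]))
    return (int(label), 0)


def label_str(label: TimeLabel) -> str:
    """Filename-friendly rendering: ``1981`` or ``1981_07``."""
    if isinstance(label, tuple):
        return f"{label[0]}_{label[1]:02d}"
    return str(label)


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of a north-up rectangular grid.

    ``(origin_x, origin_y)`` is the map coordinate of the *outer* corner of
    pixel (0, 0); row 0 is the northernmost row, so y decreases with row
    index. Pixel sizes are positive map units per pixel.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    pixel_size_x: float
    pixel_size_y: float
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size_x == 0 or self.pixel_size_y == 0:
            raise ValueError("pixel sizes must be nonzero")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        """Map x coordinate of each column's pixel centers."""
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size_x

    def y_centers(self) -> np.ndarray:
        """Map y coordinate of each row's pixel centers (decreasing)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size_y

    def approx_equal(self, other: "GridSpec", tol: float = _COORD_TOL) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.crs_id == other.crs_id
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size_x - other.pixel_size_x) <= tol
            and abs(self.pixel_size_y - other.pixel_size_y) <= tol
        )


@dataclass
class RasterCube:
    """A (time, row, col) gridded series with a validity mask.

    Parameters
    ----------
    grid
        Georeferencing shared by every time step.
    times
        Strictly increasing time labels, one per layer.
    values
        Float array of shape ``(len(times), grid.n_rows, grid.n_cols)``.
        Entries where ``valid`` is False are never read downstream.
    valid
        Boolean array of the same shape.
    freq
        One of ``"weekly"``, ``"monthly"``, ``"annual"``; states how the
        ``times`` labels are to be read.
    """

    grid: GridSpec
    times: list[TimeLabel]
    values: np.ndarray
    valid: np.ndarray
    freq: str = "annual"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        expected = (len(self.times), self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.valid.shape != expected:
            raise ValueError(f"valid shape {self.valid.shape} != {expected}")
        if self.freq not in ("weekly", "monthly", "annual"):
            raise ValueError(f"unknown freq {self.freq!r}")
        keys = [label_sort_key(t) for t in self.times]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("time labels must be strictly increasing")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def masked(self) -> np.ndarray:
        """Values with invalid cells replaced by NaN (a defensive copy)."""
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def time_index(self, label: TimeLabel) -> int:
        key = label_sort_key(label)
        for i, t in enumerate(self.times):
            if label_sort_key(t) == key:
                return i
        raise KeyError(f"time label {label!r} not in cube")

    def like(self, values: np.ndarray, valid: np.ndarray | None = None,
             times: Sequence[TimeLabel] | None = None, freq: str | None = None) -> "RasterCube":
        """A new cube on the same grid with replaced payload."""
        return RasterCube(
            grid=self.grid,
            times=list(times) if times is not None else list(self.times),
            values=values,
            valid=valid if valid is not None else np.isfinite(values),
            freq=freq if freq is not None else self.freq,
        )


def week_to_month(year: int, week: int) -> int:
    """Month containing the first day of 1-based week-of-year ``week``.

    Weeks are the fixed 7-day blocks of the NOAA weekly composites: week w
    starts on day-of-year 7*(w-1)+1. A week straddling a month boundary is
    assigned to the month containing its start date.
    """
    if week < 1 or week > 53:
        raise ValueError(f"week {week} out of range 1..53")
    start = _dt.date(year, 1, 1) + _dt.timedelta(days=7 * (week - 1))
    if start.year != year:
        # week 53 spilling over; keep it in December of its own year
        return 12
    return start.month
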