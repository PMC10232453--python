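"""Trend statistics for index time series.

Robust nonparametric trend machinery used on annual index series: the
Theil–Sen slope (median of all pairwise slopes, in index units per year),
the Mann–Kendall monotone-trend test (S statistic, tie-corrected variance,
continuity-corrected Z, two-sided normal p), a first-difference detrending
step for correlation analyses, and ordinary least-squares fits for
index-versus-reference scatter comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import RasterCube

__all__ = [
    "TrendResult", "FitResult", "detrend_diff", "theil_sen",
    "mann_kendall", "trend_map", "linear_fit",
]

#: Default two-sided significance level for "significant trend" maps.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    slope: float        # Theil–Sen slope, index units per time unit
    mk_s: int           # Mann–Kendall S
    mk_z: float         # continuity-corrected normal deviate
    p_value: float      # two-sided
    n: int


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n: int


def detrend_diff(obj: RasterCube | np.ndarray):
    """First-difference detrending: output at t is value(t) - value(t-1).

    For a cube the result has one fewer time step and is invalid wherever
    either operand is; for a plain array NaNs propagate the same way.
    """
    if isinstance(obj, RasterCube):
        if obj.n_times < 2:
            raise ValueError("detrending needs at least two time steps")
        vals = obj.values[1:] - obj.values[:-1]
        valid = obj.valid[1:] & obj.valid[:-1]
        vals = np.where(valid, vals, 0.0)
        return obj.like(vals, valid=valid, times=obj.times[1:])
    arr = np.asarray(obj, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("detrending needs at least two time steps")
    return arr[1:] - arr[:-1]


def theil_sen(y: np.ndarray, t: np.ndarray | None = None) -> float:
    """Median of all pairwise slopes (y_j - y_i) / (t_j - t_i), i < j.

    NaN entries are dropped; with fewer than two valid points with
    distinct times the slope is undefined (NaN). An even number of
    pairwise slopes yields the mean of the two central values.
    """
    y = np.asarray(y, dtype=float)
    if t is None:
        t = np.arange(len(y), dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if len(y) < 2 or len(np.unique(t)) < 2:
        return float("nan")
    slope, _, _, _ = stats.theilslopes(y, t)
    return float(slope)


def mann_kendall(y: np.ndarray) -> tuple[int, float, float]:
    """Mann–Kendall test: returns (S, Z, two-sided p).

    S sums the signs of all forward differences; the variance uses the
    tie-correction sum over tied groups, and Z applies the +/-1 continuity
    correction. NaNs are dropped. Fewer than 4 valid points give
    (S, nan, nan); an all-tied series gives (0, 0, 1).
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    n = len(y)
    if n < 2:
        return 0, float("nan"), float("nan")
    diff_signs = np.sign(y[None, :] - y[:, None])
    s = int(np.triu(diff_signs, k=1).sum())
    if n < 4:
        return s, float("nan"), float("nan")
    _, counts = np.unique(y, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    if var_s <= 0:  # every value tied
        return 0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(z), float(p)


def trend_series(y: np.ndarray, t: np.ndarray | None = None) -> TrendResult:
    """Theil–Sen slope plus Mann–Kendall test for one series."""
    y = np.asarray(y, dtype=float)
    s, z, p = mann_kendall(y)
    return TrendResult(
        slope=theil_sen(y, t), mk_s=s, mk_z=z, p_value=p,
        n=int(np.isfinite(y).sum()),
    )


def trend_map(cube: RasterCube) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel Theil–Sen slope and Mann–Kendall p-value grids.

    Pixels with fewer than 4 valid steps (or fewer than 2 distinct times)
    are NaN in both outputs. Time is measured in steps of the cube's time
    axis (per year for annual cubes).
    """
    if cube.n_times < 4:
        raise ValueError("trend mapping needs at least 4 time steps")
    vals = cube.masked()
    t = np.arange(cube.n_times, dtype=float)
    slopes = np.full(cube.grid.shape, np.nan)
    pvals = np.full(cube.grid.shape, np.nan)
    for i in range(cube.grid.n_rows):
        for j in range(cube.grid.n_cols):
            series = vals[:, i, j]
            if np.isfinite(series).sum() < 4:
                continue
            res = trend_series(series, t)
            slopes[i, j] = res.slope
            pvals[i, j] = res.p_value
    return slopes, pvals


def linear_fit(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Ordinary least squares y = slope*x + intercept with Pearson r.

    Pairs with a NaN are dropped; fewer than 3 pairs or a constant x flag
    every field NaN. p is the two-sided slope test on n-2 degrees of
    freedom (identical to the correlation test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3 or np.ptp(x[ok]) == 0:
        nan = float("nan")
        return FitResult(nan, nan, nan, nan, nan, n)
    res = stats.linregress(x[ok], y[ok])
    return FitResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue), n=n,
    )
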