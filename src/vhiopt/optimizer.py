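"""Per-pixel calibration of the VCI/TCI contribution weight.

The equal-weight VHI assumes vegetation greenness (VCI) and thermal stress
(TCI) contribute equally to vegetation health everywhere. This module
estimates, pixel by pixel, the weight a that makes the weighted index

    VHI(a) = a * VCI + (1 - a) * TCI

agree best — in the Pearson sense — with an independent reference drought
index (an sc-PDSI-like series resampled onto the same grid). The search is
a grid search over the 49 candidates a = 0.02, 0.04, ..., 0.98; the
candidate with the largest signed correlation is the pixel's optimal
contribution a_opt, and VHI built with a_opt is the optimized index
VHI_opt. Pixels whose reference overlap is too short, or whose series are
constant, are left invalid rather than poorly estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GridSpec, RasterCube
from .indices import compute_vhi

__all__ = [
    "candidate_grid", "pearson", "correlation_profile", "select_a_opt",
    "optimize_contribution", "compute_vhi_opt", "dominance_summary",
    "ContributionMap", "DEFAULT_MIN_OVERLAP",
]

#: Minimum joint-valid time steps required to estimate a pixel's weight.
DEFAULT_MIN_OVERLAP = 10

#: Minimum pairs for a defined Pearson coefficient.
_MIN_PEARSON_N = 3


def candidate_grid(step: float = 0.02) -> np.ndarray:
    """Candidate contribution weights: step, 2*step, ..., < 1 (49 for 0.02)."""
    if not (0.0 < step < 1.0):
        raise ValueError("step must lie in (0, 1)")
    n = int(round(1.0 / step)) - 1
    return np.round(np.arange(1, n + 1) * step, 10)


@dataclass
class ContributionMap:
    """Per-pixel optimal weight and the correlation achieved at it.

    ``a_opt`` and ``r_max`` are NaN where ``valid`` is False. Pixels with
    ``r_max < 0`` kept their best candidate under a negative correlation
    ceiling; users may wish to mask them.
    """

    grid: GridSpec
    a_opt: np.ndarray
    r_max: np.ndarray
    n_used: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a_opt", "r_max", "n_used", "valid"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")


def pearson(x: np.ndarray, y: np.ndarray, min_n: int = _MIN_PEARSON_N) -> float:
    """Product-moment correlation of two series; NaN where undefined.

    Pairs where either entry is non-finite are dropped. Fewer than
    ``min_n`` surviving pairs, or a constant series, flag the result as
    undefined (NaN) instead of raising, so per-pixel loops can simply mark
    the pixel invalid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_n:
        return float("nan")
    xv, yv = x[ok], y[ok]
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def correlation_profile(
    vci: np.ndarray,
    tci: np.ndarray,
    ref: np.ndarray,
    candidates: np.ndarray | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> np.ndarray:
    """Pearson r between VHI(a) and the reference, for every candidate a.

    Only time steps where all three series are finite enter; with fewer
    than ``min_overlap`` such steps every entry is NaN.
    """
    if candidates is None:
        candidates = candidate_grid()
    vci = np.asarray(vci, dtype=float)
    tci = np.asarray(tci, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not (vci.shape == tci.shape == ref.shape):
        raise ValueError("series must be time-aligned with equal lengths")
    ok = np.isfinite(vci) & np.isfinite(tci) & np.isfinite(ref)
    n = int(ok.sum())
    if n < max(min_overlap, _MIN_PEARSON_N):
        return np.full(len(candidates), np.nan)
    v, t, r = vci[ok], tci[ok], ref[ok]
    # VHI(a) for all candidates at once: shape (n_candidates, n)
    X = candidates[:, None] * v[None, :] + (1.0 - candidates)[:, None] * t[None, :]
    Xd = X - X.mean(axis=1, keepdims=True)
    rd = r - r.mean()
    num = Xd @ rd
    denom = np.sqrt((Xd * Xd).sum(axis=1) * (rd * rd).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(denom > 0, num / denom, np.nan)
    return np.clip(prof, -1.0, 1.0)


def select_a_opt(
    profile: np.ndarray, candidates: np.ndarray | None = None
) -> tuple[float, float]:
    """Argmax of the correlation profile; ties go to the smallest candidate.

    Returns ``(a_opt, r_max)``, or ``(nan, nan)`` when no entry is defined.
    The selection maximizes signed r, not |r|.
    """
    if candidates is None:
        candidates = candidate_grid()
    profile = np.asarray(profile, dtype=float)
    if profile.shape != candidates.shape:
        raise ValueError("profile and candidate grid lengths differ")
    if not np.any(np.isfinite(profile)):
        return float("nan"), float("nan")
    # np.nanargmax returns the first maximum; candidates are increasing,
    # so exact ties resolve to the smallest a.
    i = int(np.nanargmax(profile))
    return float(candidates[i]), float(profile[i])


def _check_aligned(*cubes: RasterCube) -> None:
    first = cubes[0]
    for c in cubes[1:]:
        if not c.grid.approx_equal(first.grid):
            raise ValueError("input cubes must share one grid")
        if list(c.times) != list(first.times):
            raise ValueError("input cubes must share one time axis")


def optimize_contribution(
    vci: RasterCube,
    tci: RasterCube,
    ref: RasterCube,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    candidates: np.ndarray | None = None,
) -> ContributionMap:
    """Estimate a_opt at every pixel by grid-search correlation maximization.

    The reference cube must already be on the target grid and time axis
    (see :func:`vhiopt.preprocess.resample_nearest` and
    :func:`vhiopt.preprocess.aggregate_time`). Deterministic given inputs.
    """
    _check_aligned(vci, tci, ref)
    if candidates is None:
        candidates = candidate_grid()
    n_rows, n_cols = vci.grid.shape
    a_opt = np.full((n_rows, n_cols), np.nan)
    r_max = np.full((n_rows, n_cols), np.nan)
    n_used = np.zeros((n_rows, n_cols), dtype=int)

    v_all, t_all, ref_all = vci.masked(), tci.masked(), ref.masked()
    joint = vci.valid & tci.valid & ref.valid
    for i in range(n_rows):
        for j in range(n_cols):
            n_used[i, j] = int(joint[:, i, j].sum())
            prof = correlation_profile(
                v_all[:, i, j], t_all[:, i, j], ref_all[:, i, j],
                candidates=candidates, min_overlap=min_overlap,
            )
            a_opt[i, j], r_max[i, j] = select_a_opt(prof, candidates)
    valid = np.isfinite(a_opt)
    return ContributionMap(vci.grid, a_opt, r_max, n_used, valid)


def compute_vhi_opt(vci: RasterCube, tci: RasterCube, cmap: ContributionMap) -> RasterCube:
    """VHI_opt = a_opt * VCI + (1 - a_opt) * TCI, per pixel.

    Invalid wherever the contribution map is invalid.
    """
    if not cmap.grid.approx_equal(vci.grid):
        raise ValueError("contribution map grid does not match cubes")
    return compute_vhi(vci, tci, cmap.a_opt)


def dominance_summary(cmap: ContributionMap) -> tuple[float, float]:
    """Fractions of valid pixels that are TCI-dominated (a_opt < 0.5) and
    VCI-dominated (a_opt > 0.5).

    The candidate grid contains 0.5 itself (25 * 0.02), so pixels whose
    optimum is exactly balanced belong to neither fraction and the two
    fractions sum to at most 1.
    """
    a = cmap.a_opt[cmap.valid]
    if a.size == 0:
        raise ValueError("contribution map has no valid pixels")
    return float((a < 0.5).mean()), float((a > 0.5).mean())
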