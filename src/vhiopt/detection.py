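"""Drought-event detection scoring.

Given an annual VHI cube and a catalog of recorded drought events (year
plus affected region), each event is scored by the fraction of the
region's valid pixels the index flags as drought (VHI at or below 40) in
the event year:

    score = 1    if the flagged fraction exceeds 80%
    score = 0.5  if it exceeds 40% (but not 80%)
    score = 0    otherwise

and the detection efficiency of the index over a catalog is

    DTE = 100 * (sum of scores) / (number of events).

Event regions are geometry (a bounding box in map coordinates or a boolean
mask raster); mapping archive records to geometry is the caller's job.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GridSpec, RasterCube
from .indices import DEFAULT_THRESHOLD, drought_mask

__all__ = [
    "DroughtEvent", "EventScore", "DetectionReport",
    "region_mask", "score_event", "detection_efficiency", "compare_indices",
    "read_event_catalog", "write_report",
]


@dataclass(frozen=True)
class DroughtEvent:
    """One catalog record: an event year plus its affected region.

    The region is either ``box = (min_x, min_y, max_x, max_y)`` in map
    coordinates (pixels whose centers fall inside, half-open on the max
    edges) or ``mask``, a boolean grid matching the cube.
    """

    event_id: str
    year: int
    box: tuple[float, float, float, float] | None = None
    mask: np.ndarray | None = None
    continent: str | None = None

    def __post_init__(self) -> None:
        if (self.box is None) == (self.mask is None):
            raise ValueError(f"event {self.event_id}: exactly one of box/mask required")


@dataclass(frozen=True)
class EventScore:
    event_id: str
    year: int
    n_region_pixels: int
    n_drought_pixels: int
    fraction: float
    score: float
    continent: str | None = None


@dataclass(frozen=True)
class DetectionReport:
    scores: tuple[EventScore, ...]
    total_events: int
    total_score: float
    dte: float


def region_mask(event: DroughtEvent, grid: GridSpec) -> np.ndarray:
    """Boolean pixel mask of the event's region on ``grid``.

    Raises if the region touches no pixel center.
    """
    if event.mask is not None:
        mask = np.asarray(event.mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError(
                f"event {event.event_id}: mask shape {mask.shape} != grid {grid.shape}"
            )
    else:
        min_x, min_y, max_x, max_y = event.box  # type: ignore[misc]
        xs = grid.x_centers()
        ys = grid.y_centers()
        in_x = (xs >= min_x) & (xs < max_x)
        in_y = (ys >= min_y) & (ys < max_y)
        mask = in_y[:, None] & in_x[None, :]
    if not mask.any():
        raise ValueError(f"event {event.event_id}: region intersects no grid pixel")
    return mask


def score_event(
    vhi_annual: RasterCube,
    event: DroughtEvent,
    threshold: float = DEFAULT_THRESHOLD,
    boundary_inclusive: bool = True,
) -> EventScore:
    """Score one event against the annual VHI cube.

    The denominator counts only valid pixels of the region in the event
    year. The 80% and 40% cuts are strict ("more than"): a fraction of
    exactly 0.8 scores 0.5 and exactly 0.4 scores 0.
    """
    t = vhi_annual.time_index(event.year)
    region = region_mask(event, vhi_annual.grid)
    valid = vhi_annual.valid[t] & region
    n_region = int(valid.sum())
    if n_region == 0:
        raise ValueError(f"event {event.event_id}: no valid pixels in region in {event.year}")
    flags = drought_mask(vhi_annual, threshold, boundary_inclusive)
    n_drought = int((flags.values[t].astype(bool) & valid).sum())
    fraction = n_drought / n_region
    if fraction > 0.8:
        score = 1.0
    elif fraction > 0.4:
        score = 0.5
    else:
        score = 0.0
    return EventScore(
        event_id=event.event_id, year=event.year,
        n_region_pixels=n_region, n_drought_pixels=n_drought,
        fraction=fraction, score=score, continent=event.continent,
    )


def detection_efficiency(scores: Sequence[EventScore]) -> DetectionReport:
    """DTE = 100 * S / TDE over a list of event scores."""
    if len(scores) == 0:
        raise ValueError("no events to evaluate")
    total = float(sum(s.score for s in scores))
    return DetectionReport(
        scores=tuple(scores),
        total_events=len(scores),
        total_score=total,
        dte=100.0 * total / len(scores),
    )


def stratified_efficiency(
    scores: Sequence[EventScore], key: str
) -> dict[object, DetectionReport]:
    """Per-group reports keyed by an EventScore attribute (``year``/``continent``)."""
    groups: dict[object, list[EventScore]] = {}
    for s in scores:
        groups.setdefault(getattr(s, key), []).append(s)
    return {k: detection_efficiency(v) for k, v in sorted(groups.items(), key=lambda kv: str(kv[0]))}


def compare_indices(
    vhi_a: RasterCube,
    vhi_b: RasterCube,
    events: Sequence[DroughtEvent],
    threshold: float = DEFAULT_THRESHOLD,
    boundary_inclusive: bool = True,
) -> dict:
    """Score one event list against two VHI cubes (e.g. optimized vs original).

    Returns both reports plus per-year counts of detected events
    (score > 0) for histogram plotting.
    """
    if not vhi_a.grid.approx_equal(vhi_b.grid) or list(vhi_a.times) != list(vhi_b.times):
        raise ValueError("the two cubes must share one grid and time axis")
    reports = {}
    detected_by_year: dict[str, dict[int, int]] = {}
    for name, cube in (("a", vhi_a), ("b", vhi_b)):
        scores = [score_event(cube, e, threshold, boundary_inclusive) for e in events]
        reports[name] = detection_efficiency(scores)
        per_year: dict[int, int] = {}
        for s in scores:
            per_year[s.year] = per_year.get(s.year, 0) + (1 if s.score > 0 else 0)
        detected_by_year[name] = dict(sorted(per_year.items()))
    return {"report_a": reports["a"], "report_b": reports["b"],
            "detected_by_year": detected_by_year}


def read_event_catalog(path: str | os.PathLike) -> list[DroughtEvent]:
    """Load events from CSV.

    Columns: ``event_id, year, min_lon, min_lat, max_lon, max_lat`` and
    optional ``continent``. Missing box columns require ``mask_path``, a
    GeoTIFF whose nonzero cells form the region.
    """
    df = pd.read_csv(path)
    required = {"event_id", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event catalog missing columns: {sorted(missing)}")
    events: list[DroughtEvent] = []
    for _, row in df.iterrows():
        box = None
        mask = None
        if {"min_lon", "min_lat", "max_lon", "max_lat"} <= set(df.columns) and np.isfinite(row["min_lon"]):
            box = (float(row["min_lon"]), float(row["min_lat"]),
                   float(row["max_lon"]), float(row["max_lat"]))
        elif "mask_path" in df.columns and isinstance(row["mask_path"], str):
            from .io import _read_page
            data, _, _ = _read_page(Path(row["mask_path"]))
            mask = data != 0
        continent = row["continent"] if "continent" in df.columns and isinstance(row.get("continent"), str) else None
        events.append(DroughtEvent(
            event_id=str(row["event_id"]), year=int(row["year"]),
            box=box, mask=mask, continent=continent,
        ))
    return events


def write_report(report: DetectionReport, path: str | os.PathLike) -> None:
    """Per-event rows plus a summary row, as CSV."""
    rows = [
        {
            "event_id": s.event_id, "year": s.year, "continent": s.continent,
            "n_region_pixels": s.n_region_pixels,
            "n_drought_pixels": s.n_drought_pixels,
            "fraction": s.fraction, "score": s.score,
        }
        for s in report.scores
    ]
    rows.append({
        "event_id": "TOTAL", "year": "", "continent": "",
        "n_region_pixels": "", "n_drought_pixels": "",
        "fraction": "", "score": report.total_score,
    })
    df = pd.DataFrame(rows)
    df.attrs["dte"] = report.dte
    df.to_csv(path, index=False)
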