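"""End-to-end workflow: preprocess -> indices -> calibrate -> detect -> trends.

A :class:`PipelineConfig` (loadable from YAML, unknown keys rejected)
names the input directories and options; :func:`run_pipeline` executes the
stages and writes a JSON manifest listing every output file with its
SHA-256 hash, so identical inputs provably yield identical outputs. Any
stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import RasterCube
from .detection import compare_indices, read_event_catalog, write_report
from .indices import (
    BASELINE_WEIGHT, DEFAULT_THRESHOLD, compute_tci, compute_vci, compute_vhi,
)
from .io import DEFAULT_NODATA, read_cube, write_cube, write_field
from .optimizer import DEFAULT_MIN_OVERLAP, candidate_grid, compute_vhi_opt, optimize_contribution
from .preprocess import aggregate_time, resample_nearest
from .trends import trend_map

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "read_cube_dir"]

logger = logging.getLogger("vhiopt")

_YEAR_RE = re.compile(r"(\d{4})")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``vci_dir``/``tci_dir`` (precomputed indices) or
    ``ndvi_dir``/``lst_dir`` (raw inputs, indices computed here) must be
    set, plus ``ref_dir`` with the reference drought-index series.
    """

    out_dir: str = "vhiopt_out"
    vci_dir: str | None = None
    tci_dir: str | None = None
    ndvi_dir: str | None = None
    lst_dir: str | None = None
    ref_dir: str | None = None
    events_file: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    boundary_inclusive: bool = True
    candidate_step: float = 0.02
    min_overlap: int = DEFAULT_MIN_OVERLAP
    background_value: float = DEFAULT_NODATA
    run_trends: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_cube_dir(
    directory: str | Path,
    background_value: float = DEFAULT_NODATA,
    freq: str = "annual",
) -> RasterCube:
    """Read every ``*.tif`` in a directory as an annual cube.

    The time label of each file is the four-digit year in its name.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no .tif files in {directory}")
    labeled = []
    for p in paths:
        m = _YEAR_RE.search(p.stem)
        if not m:
            raise ValueError(f"cannot parse a year from filename {p.name}")
        labeled.append((int(m.group(1)), p))
    labeled.sort()
    years = [y for y, _ in labeled]
    if len(set(years)) != len(years):
        raise ValueError(f"duplicate years among files in {directory}")
    return read_cube([p for _, p in labeled], years, background_value, freq=freq)


def _select_times(cube: RasterCube, labels: list) -> RasterCube:
    idx = [cube.time_index(t) for t in labels]
    return RasterCube(cube.grid, labels, cube.values[idx], cube.valid[idx], freq=cube.freq)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow; return (and write) the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- stage: preprocess (load inputs) -------------------------------
    stage = "preprocess"
    try:
        if config.vci_dir and config.tci_dir:
            vci = read_cube_dir(config.vci_dir, config.background_value)
            tci = read_cube_dir(config.tci_dir, config.background_value)
        elif config.ndvi_dir and config.lst_dir:
            ndvi = read_cube_dir(config.ndvi_dir, config.background_value)
            lst = read_cube_dir(config.lst_dir, config.background_value)
        else:
            raise ValueError("config needs vci_dir+tci_dir or ndvi_dir+lst_dir")
        if not config.ref_dir:
            raise ValueError("config needs ref_dir (reference drought index)")
        ref = read_cube_dir(config.ref_dir, config.background_value)
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: indices ------------------------------------------------
    stage = "indices"
    try:
        if config.ndvi_dir and not (config.vci_dir and config.tci_dir):
            vci = compute_vci(ndvi)
            tci = compute_tci(lst)
            outputs += write_cube(vci, out_dir / "vci", "VCI_{year}.tif")
            outputs += write_cube(tci, out_dir / "tci", "TCI_{year}.tif")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: optimize -----------------------------------------------
    stage = "optimize"
    try:
        if not ref.grid.approx_equal(vci.grid):
            ref = resample_nearest(ref, vci.grid)
        if ref.freq != "annual":
            ref = aggregate_time(ref, "annual")
        common = [t for t in vci.times if t in set(ref.times)]
        if not common:
            raise ValueError("no overlapping years between indices and reference")
        cmap = optimize_contribution(
            _select_times(vci, common), _select_times(tci, common),
            _select_times(ref, common),
            min_overlap=config.min_overlap,
            candidates=candidate_grid(config.candidate_step),
        )
        outputs.append(write_field(cmap.a_opt, cmap.valid, cmap.grid, out_dir / "a_opt.tif"))
        outputs.append(write_field(cmap.r_max, cmap.valid, cmap.grid, out_dir / "r_max.tif"))
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: vhi_opt ------------------------------------------------
    stage = "vhi_opt"
    try:
        vhi_opt = compute_vhi_opt(vci, tci, cmap)
        outputs += write_cube(vhi_opt, out_dir / "vhi_opt", "VHIopt_{year}.tif")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: detect (optional) --------------------------------------
    detection_summary = None
    if config.events_file:
        stage = "detect"
        try:
            events = read_event_catalog(config.events_file)
            vhi_ori = compute_vhi(vci, tci, BASELINE_WEIGHT)
            cmp = compare_indices(
                vhi_opt, vhi_ori, events,
                threshold=config.threshold,
                boundary_inclusive=config.boundary_inclusive,
            )
            write_report(cmp["report_a"], out_dir / "detection_vhi_opt.csv")
            write_report(cmp["report_b"], out_dir / "detection_vhi_ori.csv")
            outputs += [out_dir / "detection_vhi_opt.csv", out_dir / "detection_vhi_ori.csv"]
            detection_summary = {
                "dte_vhi_opt": cmp["report_a"].dte,
                "dte_vhi_ori": cmp["report_b"].dte,
            }
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- stage: trends (optional) --------------------------------------
    if config.run_trends:
        stage = "trends"
        try:
            slopes, pvals = trend_map(vhi_opt)
            ok = np.isfinite(slopes)
            outputs.append(write_field(slopes, ok, vhi_opt.grid, out_dir / "trend_slope.tif"))
            outputs.append(write_field(pvals, np.isfinite(pvals), vhi_opt.grid, out_dir / "trend_p.tif"))
        except ValueError as exc:
            raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {
            str(p.relative_to(out_dir)): _sha256(p) for p in sorted(outputs)
        },
    }
    if detection_summary:
        manifest["detection"] = detection_summary
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return manifest
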