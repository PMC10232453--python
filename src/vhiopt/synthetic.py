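"""Synthetic co-registered index cubes with known ground truth.

Every downstream module — index computation, weight calibration, drought
scoring, trend mapping — is testable without satellite archives by
generating scenes whose true per-pixel mixing weights, drought events, and
trends are known by construction.

Per pixel, two independent latent series V and T (standardized to sample
mean 0, sd 1) play the roles of the greenness and thermal anomaly signals.
Both are mapped into valid index cubes with one shared per-pixel gain,

    VCI = base + g * V,    TCI = base + g * T,

so VCI and TCI have exactly equal sample variance — the regime in which
the correlation-maximizing weight is identifiable — while staying inside
[0, 100]. The reference drought index is the true mixture plus noise,

    ref = a_true * V + (1 - a_true) * T + eps,   sd(eps) = sd(mixture)/snr,

so the calibration problem has a known answer a_true at every pixel.

Drought events subtract a severity from the indices *along the true mixing
direction* (dVCI proportional to a_true, dTCI to 1 - a_true, scaled so VHI
at the true weight drops by exactly the severity): an event is a drought
of the pixel's true moisture signal, which a correctly weighted index sees
at full depth and the equal-weight index sees attenuated. Optional linear
trends are added to both indices for trend-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GridSpec, RasterCube
from .detection import DroughtEvent, EventScore, score_event
from .indices import DEFAULT_THRESHOLD, compute_vhi

__all__ = [
    "EventSpec", "SyntheticScenario", "SyntheticTruth",
    "generate_cubes", "generate_event_catalog",
    "default_scenario", "detection_scenario",
]


@dataclass(frozen=True)
class EventSpec:
    """A drought to inject: year, pixel-index region (half-open), severity.

    ``severity`` is the drop, in VHI units, of the true-weight VHI inside
    the region in that year; 0 defines a no-drought control event.
    """

    event_id: str
    year: int
    row0: int
    row1: int
    col0: int
    col1: int
    severity: float
    continent: str | None = None


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator configuration; same scenario + seed give identical cubes.

    ``a_true`` is a scalar weight, the string ``"gradient"`` (weights
    spanning 0.1..0.9 across columns), ``"random"`` (uniform 0.1..0.9), or
    an explicit per-pixel array. ``snr`` is the ratio of mixed-signal to
    noise standard deviation (``inf`` for noiseless). ``trend`` is a
    per-year slope added to both indices (scalar or per-pixel).
    """

    n_rows: int = 32
    n_cols: int = 32
    n_years: int = 41
    start_year: int = 1981
    a_true: object = "gradient"
    snr: float = 10.0
    base: float = 50.0
    gain: float = 15.0
    ar1: float = 0.0
    trend: object = 0.0
    events: tuple[EventSpec, ...] = ()
    seed: int = 0
    origin_x: float = 10.0
    origin_y: float = 50.0
    pixel_size: float = 0.05
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_years < 2:
            raise ValueError("grid dims must be >= 1 and n_years >= 2")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows, n_cols=self.n_cols,
            origin_x=self.origin_x, origin_y=self.origin_y,
            pixel_size_x=self.pixel_size, pixel_size_y=self.pixel_size,
            crs_id=self.crs_id,
        )

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def a_true_grid(self) -> np.ndarray:
        shape = (self.n_rows, self.n_cols)
        if isinstance(self.a_true, str):
            if self.a_true == "gradient":
                col_w = np.linspace(0.1, 0.9, self.n_cols)
                return np.broadcast_to(col_w, shape).copy()
            if self.a_true == "random":
                rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
                return rng.uniform(0.1, 0.9, size=shape)
            raise ValueError(f"unknown a_true mode {self.a_true!r}")
        a = np.asarray(self.a_true, dtype=float)
        if a.ndim == 0:
            a = np.full(shape, float(a))
        if a.shape != shape:
            raise ValueError(f"a_true shape {a.shape} != grid {shape}")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("a_true must lie in [0, 1]")
        return a

    def event_box(self, ev: EventSpec) -> tuple[float, float, float, float]:
        """Map-coordinate bounding box of an event's pixel-index region."""
        if not (0 <= ev.row0 < ev.row1 <= self.n_rows
                and 0 <= ev.col0 < ev.col1 <= self.n_cols):
            raise ValueError(f"event {ev.event_id}: region outside grid")
        ps = self.pixel_size
        return (
            self.origin_x + ev.col0 * ps,
            self.origin_y - ev.row1 * ps,
            self.origin_x + ev.col1 * ps,
            self.origin_y - ev.row0 * ps,
        )


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated scene."""

    a_true: np.ndarray
    trend: np.ndarray
    events: list[DroughtEvent]
    expected_scores: list[EventScore]


def _standardized_latents(scenario: SyntheticScenario, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape = (scenario.n_years, scenario.n_rows, scenario.n_cols)
    v = rng.standard_normal(shape)
    t = rng.standard_normal(shape)
    if scenario.ar1 > 0:
        phi = scenario.ar1
        for k in range(1, scenario.n_years):
            v[k] = phi * v[k - 1] + np.sqrt(1 - phi**2) * v[k]
            t[k] = phi * t[k - 1] + np.sqrt(1 - phi**2) * t[k]
    for arr in (v, t):
        arr -= arr.mean(axis=0)
        arr /= arr.std(axis=0)
    return v, t


def generate_cubes(
    scenario: SyntheticScenario,
) -> tuple[RasterCube, RasterCube, RasterCube, SyntheticTruth]:
    """Generate (vci, tci, ref) cubes plus their ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))
    v, t = _standardized_latents(scenario, rng)
    a = scenario.a_true_grid()

    # one shared gain per pixel keeps VCI/TCI sample sds equal and the
    # values inside [0, 100]
    headroom = min(scenario.base, 100.0 - scenario.base) - 0.1
    max_abs = np.maximum(np.abs(v).max(axis=0), np.abs(t).max(axis=0))
    g = np.minimum(scenario.gain, headroom / max_abs)
    vci_vals = scenario.base + g[None] * v
    tci_vals = scenario.base + g[None] * t

    mix = a[None] * v + (1.0 - a)[None] * t
    ref_vals = mix.copy()
    if np.isfinite(scenario.snr):
        noise_sd = mix.std(axis=0) / scenario.snr
        ref_vals = ref_vals + noise_sd[None] * rng.standard_normal(mix.shape)

    trend = np.asarray(scenario.trend, dtype=float)
    if trend.ndim == 0:
        trend = np.full((scenario.n_rows, scenario.n_cols), float(trend))
    if np.any(trend != 0):
        tt = np.arange(scenario.n_years) - (scenario.n_years - 1) / 2.0
        ramp = trend[None] * tt[:, None, None]
        vci_vals = vci_vals + ramp
        tci_vals = tci_vals + ramp

    # droughts: subtract severity along the true mixing direction so the
    # true-weight VHI drops by exactly `severity` in the region
    year_index = {y: i for i, y in enumerate(scenario.years)}
    norm = a**2 + (1.0 - a) ** 2
    for ev in scenario.events:
        scenario.event_box(ev)  # validates the region
        if ev.year not in year_index:
            raise ValueError(f"event {ev.event_id}: year {ev.year} outside scenario")
        k = year_index[ev.year]
        rs, cs = slice(ev.row0, ev.row1), slice(ev.col0, ev.col1)
        vci_vals[k, rs, cs] -= ev.severity * a[rs, cs] / norm[rs, cs]
        tci_vals[k, rs, cs] -= ev.severity * (1.0 - a[rs, cs]) / norm[rs, cs]

    vci_vals = np.clip(vci_vals, 0.0, 100.0)
    tci_vals = np.clip(tci_vals, 0.0, 100.0)

    grid = scenario.grid
    years = scenario.years
    all_valid = np.ones(vci_vals.shape, dtype=bool)
    vci = RasterCube(grid, years, vci_vals, all_valid.copy(), freq="annual")
    tci = RasterCube(grid, years, tci_vals, all_valid.copy(), freq="annual")
    ref = RasterCube(grid, years, ref_vals, all_valid.copy(), freq="annual")

    events = [
        DroughtEvent(
            event_id=ev.event_id, year=ev.year,
            box=scenario.event_box(ev), continent=ev.continent,
        )
        for ev in scenario.events
    ]
    vhi_true = compute_vhi(vci, tci, a)
    expected = [score_event(vhi_true, e, DEFAULT_THRESHOLD) for e in events]
    truth = SyntheticTruth(a_true=a, trend=trend, events=events, expected_scores=expected)
    return vci, tci, ref, truth


def generate_event_catalog(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, list[EventScore]]:
    """Event catalog rows (CSV schema) plus expected scores.

    The expected score of each event is computed by applying the scoring
    rule to the VHI built with the *true* weights on the generated scene —
    what a perfectly calibrated index would report.
    """
    if not scenario.events:
        raise ValueError("scenario has no drought events")
    _, _, _, truth = generate_cubes(scenario)
    rows = []
    for ev, spec in zip(truth.events, scenario.events):
        min_x, min_y, max_x, max_y = ev.box  # type: ignore[misc]
        rows.append({
            "event_id": ev.event_id, "year": ev.year,
            "min_lon": min_x, "min_lat": min_y,
            "max_lon": max_x, "max_lat": max_y,
            "continent": ev.continent, "severity": spec.severity,
        })
    return pd.DataFrame(rows), truth.expected_scores


def scenario_from_dict(raw: dict) -> SyntheticScenario:
    """Build a scenario from a plain mapping (e.g. parsed YAML).

    Unknown keys are rejected; ``events`` entries are mappings with the
    :class:`EventSpec` fields.
    """
    import dataclasses as _dc

    raw = dict(raw)
    events = raw.pop("events", [])
    known = {f.name for f in _dc.fields(SyntheticScenario)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    ev_known = {f.name for f in _dc.fields(EventSpec)}
    specs = []
    for ev in events:
        bad = set(ev) - ev_known
        if bad:
            raise ValueError(f"unknown event keys: {sorted(bad)}")
        specs.append(EventSpec(**ev))
    return SyntheticScenario(events=tuple(specs), **raw)


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The reference calibration scenario: 32x32 pixels, 41 annual steps
    (the 1981–2021 span of the weekly vegetation-health archive), snr 10,
    per-pixel true weights spanning 0.1–0.9."""
    return SyntheticScenario(seed=seed)


def detection_scenario(seed: int = 0) -> SyntheticScenario:
    """A detection-evaluation scene: TCI-dominated truth (a_true = 0.2, as
    most of the world is in the calibrated product) plus five events whose
    severities span clear drought, marginal drought, and control."""
    events = (
        EventSpec("ev-severe", 1990, 4, 20, 4, 20, severity=30.0, continent="A"),
        EventSpec("ev-strong", 1995, 12, 28, 12, 28, severity=22.0, continent="A"),
        EventSpec("ev-moderate", 2000, 4, 20, 12, 28, severity=12.0, continent="B"),
        EventSpec("ev-mild", 2005, 12, 28, 4, 20, severity=8.0, continent="B"),
        EventSpec("ev-control", 2010, 8, 24, 8, 24, severity=0.0, continent="B"),
    )
    return SyntheticScenario(a_true=0.2, events=events, seed=seed)
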