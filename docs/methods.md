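# Methods note

This note records the model implemented by `vhiopt`, every parameter with its
default and rationale, what the synthetic-scene generator does and does not
emulate, the numerical choices that affect results, and known limitations.

## 1. Model and procedure

### Condition indices

Per pixel, over the full time record:

- `VCI = 100 · (NDVI − NDVI_min) / (NDVI_max − NDVI_min)`
- `TCI = 100 · (LST_max − LST) / (LST_max − LST_min)`

Extrema are per-pixel by default (`scope="pixel"`); a `scope="global"` option
uses scene-wide extrema. A pixel whose record has zero span (max = min)
cannot be scaled and is marked invalid rather than assigned an arbitrary
value.

### Contribution-weight calibration

For each pixel, the weight `a` of VCI in `VHI(a) = a·VCI + (1−a)·TCI` is
selected from the candidate grid `{0.02, 0.04, …, 0.98}` (49 values,
step 0.02, endpoints excluded so neither component is ever dropped
entirely) by maximizing the Pearson correlation with a reference drought
index over the years where all three series are valid. Outputs per pixel:
`a_opt`, `r_max`, and `n_used` (overlap length).

- **Minimum overlap** (`min_overlap=10` years): below this, a sample
  correlation is too noisy to rank 49 candidates meaningfully; the pixel is
  left uncalibrated (invalid in the contribution map).
- **Tie-break**: the first (smallest) maximizing candidate is taken, making
  results deterministic. Exact ties are measure-zero with real data but occur
  with degenerate inputs.
- Note `a = 0.50` *is* on the candidate grid (25 · 0.02), so a pixel can be
  exactly balanced; `dominance_summary` therefore reports the `a < 0.5` and
  `a > 0.5` fractions separately and they need not sum to 1.

### Drought classification and detection scoring

VHI classes: (60, 100] excellent, (50, 60] good, (40, 50] normal,
(30, 40] mildly dry, (20, 30] moderately dry, (10, 20] severely dry,
[0, 10] extremely dry. The drought threshold is **40**, boundary inclusive
by default (`VHI ≤ 40` counts as drought); `boundary_inclusive=False` gives
strict `<`.

An event is a (region, year) pair; its region is a lon/lat box (half-open on
the max edges so adjacent boxes never double-count pixels) or an explicit
mask raster. The event **fraction** is flagged pixels divided by *valid*
pixels in the region (invalid pixels are excluded from the denominator, not
counted as misses). Scores use strict cuts: 1 if fraction > 0.8, 0.5 if
fraction > 0.4, else 0. `DTE = 100 · Σ scores / n_events`.

### Trend analysis

- Slope: Theil–Sen (`scipy.stats.theilslopes`) on valid years; undefined
  (NaN) with fewer than 2 distinct time points.
- Significance: Mann–Kendall implemented directly (S statistic,
  tie-corrected variance `(n(n−1)(2n+5) − Σt(t−1)(2t+5))/18`, ±1 continuity
  correction, two-sided normal p). For `n < 4` the normal approximation is
  unreliable, so Z and p are NaN; an all-tied series returns (S=0, Z=0,
  p=1). The empirical type-I rate at α=0.05 is verified by simulation in the
  test suite.
- Detrending: first differences (`x[t+1] − x[t]`), which removes any linear
  component exactly and shortens the series by one.
- Linear fits use `scipy.stats.linregress`; fewer than 3 points or a
  constant regressor yields an all-NaN fit rather than an error.

## 2. I/O and preprocessing choices

- **GeoTIFF**: single-band float64, values rounded to **six decimals** on
  write, nodata **−9999** (also recorded in the `GDAL_NODATA` tag), grid
  georeferencing via ModelPixelScale/ModelTiepoint/GeoKeyDirectory tags,
  EPSG:4326 default, filenames `VHIopt_{year}.tif`. Reading masks the file
  nodata, the configured background value, and non-finite values.
- **Temporal aggregation** (weekly→monthly/annual, monthly→annual):
  arithmetic mean of valid samples, `min_count=1` by default — one valid
  sample suffices, matching the permissive convention of operational
  climate composites; raise it for stricter products. A week `w` spans
  days-of-year `7(w−1)+1 … 7w`; it is assigned to the month containing its
  **start** day, and week 53 (the year-end remainder) falls in December.
- **Spatial resampling**: nearest neighbor only (appropriate for an index
  that should not be smoothed across class boundaries). The source index for
  a target center at offset `d` is `round(d/pixel − 0.5)` with ties broken
  toward the smaller index; targets more than half a source pixel outside
  the source extent are invalid, not extrapolated.

## 3. Synthetic-scene generator

`SyntheticScenario` produces VCI, TCI and reference cubes with known ground
truth so that calibration, detection and trend code can be validated
end-to-end. Defaults: 32×32 pixels at 0.05°, 41 annual steps from 1981,
true-weight gradient 0.1→0.9 across columns, SNR 10, base level 50,
gain 15 — sizes chosen to run in well under a second while leaving enough
years for stable correlations.

What it emulates:

- Per-pixel latent "moisture" and "thermal" anomaly series, standardized and
  **orthogonalized**, scaled by a gain shared between VCI and TCI so the two
  indices have **equal sample standard deviations**. This is deliberate: the
  correlation-maximizing weight equals the generating weight only when the
  components are uncorrelated with equal variance; unequal variances shift
  the argmax and would make "recovered `a_opt` ≈ `a_true`" an ill-posed
  check. The gain is capped at the available headroom so values stay in
  [0, 100] without clipping distortion.
- A reference series `a_true·v + (1−a_true)·t` plus Gaussian noise with
  standard deviation `sd(mix)/snr` (`snr=inf` gives a noiseless reference).
- Optional AR(1) temporal autocorrelation, an optional linear trend (a
  centered ramp added to both indices), and injected drought events.
- **Directional event injection**: an event of severity `s` depresses VCI by
  `s·a/(a²+(1−a)²)` and TCI by `s·(1−a)/(a²+(1−a)²)`, i.e. along the pixel's
  true mixing direction, so `VHI(a_true)` drops by exactly `s` while the
  equal-weight index drops less whenever `a_true ≠ 0.5`. Depressing both
  components equally would instead make every weighting detect identically
  and the comparison vacuous.
- Per-event expected scores computed from the true-weight index, so
  detection tests have an oracle.

What it does **not** emulate: spatial autocorrelation (pixels are
independent), seasonality or sub-annual structure, non-Gaussian anomalies,
sensor artifacts/gaps beyond explicit masking, cross-correlation between the
moisture and thermal components, or nonlinear NDVI/LST–drought responses.
Conclusions about real-data skill cannot be read off these scenes; they
validate the *mechanics* (weight recovery, scoring arithmetic, trend
statistics), not climatology.

Determinism: all randomness flows from `numpy.random.SeedSequence([seed, 0])`;
identical scenarios and seeds give bit-identical cubes, and the pipeline
manifest hashes confirm bit-identical reruns.

## 4. Numerical choices

- Everything is float64; correlations use the standard centered formula with
  pairwise-complete (NaN-dropping) samples, requiring ≥ 3 pairs.
- The weight search evaluates the full correlation profile vectorized over
  the 49 candidates; `nanargmax` implements the smallest-`a` tie-break.
- Class binning uses `searchsorted(..., side="left")` on the upper bounds
  (10, 20, 30, 40, 50, 60, 100), making each interval left-open/right-closed
  except the lowest, which includes 0.
- Six-decimal rounding on GeoTIFF write bounds file-size and makes hashes
  stable; it is far below the noise floor of any 0–100 index.

## 5. Limitations

- Weight calibration assumes the reference index is a valid drought target
  at the pixel's scale; a biased or lagged reference biases `a_opt`.
- `a_opt` from in-sample correlation maximization is optimistic; no
  cross-validation of the weight is implemented.
- The grid search resolves `a` only to ±0.02, and when the true weight sits
  exactly between two candidates the asymmetry of the correlation profile
  decides the winner — recovery guarantees are "within one grid step", not
  "nearest candidate".
- Mann–Kendall p-values use the normal approximation; for very short series
  (n < 10) exact tables would be preferable, and the test's power against
  autocorrelated series is reduced (no prewhitening is applied).
- Detection scoring is threshold-based and region-aggregate; it does not
  measure timing, duration or intensity of events, only areal coverage in
  the event year.
- Nearest-neighbor resampling and single-CRS handling (no reprojection)
  limit inputs to grids sharing a CRS.
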