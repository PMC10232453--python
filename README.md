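# vhiopt

Optimized Vegetation Health Index (VHI) construction, drought detection and
trend analysis for gridded annual (or weekly/monthly) remote-sensing data.

## The problem

The Vegetation Health Index is the workhorse satellite drought indicator. It
blends two condition indices computed per pixel from a multi-year record:

- **VCI** (Vegetation Condition Index), a min–max scaling of NDVI:
  `VCI = 100 · (NDVI − NDVI_min) / (NDVI_max − NDVI_min)`
- **TCI** (Temperature Condition Index), the inverted scaling of land-surface
  temperature: `TCI = 100 · (LST_max − LST) / (LST_max − LST_min)`

The classical index mixes them with a fixed equal weight,

```
VHI_ori = 0.5 · VCI + 0.5 · TCI
```

but the true contribution of moisture versus thermal stress varies with
climate and land cover: an equal weight under-reads drought where one
component dominates. This package calibrates the weight **per pixel**.

## The model

For each pixel, the contribution weight `a` is chosen from the candidate grid

```
a ∈ {0.02, 0.04, …, 0.98}        (49 candidates, step 0.02)
```

by maximizing the Pearson correlation between `VHI(a) = a·VCI + (1−a)·TCI`
and a reference drought index time series (e.g. a self-calibrating Palmer
index) on the overlapping valid years. The maximizing weight `a_opt` and its
correlation `r_max` form the contribution map; the optimized index is

```
VHI_opt = a_opt · VCI + (1 − a_opt) · TCI
```

VHI values fall in [0, 100] and are binned into seven classes from
*extremely dry* (0–10] through *mildly dry* (30–40] to *excellent*
(60–100]; values at or below 40 indicate vegetation drought.

Detection skill is summarized against a catalog of known drought events.
For each event the fraction of valid pixels in its region/year with
VHI ≤ 40 is computed and scored 1 (fraction > 0.8), 0.5 (> 0.4) or 0;
the **drought detection efficiency** is `DTE = 100 · Σ scores / (number of
events)`. Long-term change is mapped with per-pixel Theil–Sen slopes and
Mann–Kendall significance tests, with first-difference detrending available
for correlation analyses.

## Worked example

`examples/03_detection_efficiency.py` builds a synthetic TCI-dominated scene
(16° box, 32×32 pixels, 41 years) with five injected drought events of known
severity, calibrates the weights against the scene's noisy reference index,
and scores both indices on the same catalog:

```text
event        year  severity  frac_opt  frac_ori  score_opt  score_ori
ev-severe    1990      30.0      0.92      0.86        1.0        1.0
ev-strong    1995      22.0      0.82      0.69        1.0        0.5
ev-moderate  2000      12.0      0.50      0.41        0.5        0.5
ev-mild      2005       8.0      0.48      0.36        0.5        0.0
ev-control   2010       0.0      0.20      0.17        0.0        0.0

DTE (VHI_opt): 60.00%
DTE (VHI_ori): 40.00%
```

The calibrated index flags a larger pixel fraction on every real event and
stays silent on the no-drought control. Weight recovery itself is tight:
`examples/02_calibrate_weights.py` (gradient of true weights, SNR 10) reports
a median `|a_opt − a_true|` of 0.007 with 99.8 % of pixels within two grid
steps of truth.

The other examples cover index construction and classification (`01`), trend
mapping and detrended correlation (`04`), and the full disk-to-manifest
pipeline (`05`). Each runs in seconds:

```bash
python examples/03_detection_efficiency.py
```

## Command line

The `vhiopt` CLI wraps the library:

```bash
vhiopt simulate --seed 1 --out scene/         # synthetic VCI/TCI/ref GeoTIFFs + events.csv
vhiopt optimize --vci scene/vci --tci scene/tci --ref scene/ref --out out/
vhiopt detect   --vhi out/ --events scene/events.csv
vhiopt trends   --vhi out/ --out out/
vhiopt run      --config pipeline.yaml        # everything, with a hashed manifest
```

Inputs and outputs are single-band float GeoTIFFs, one file per year
(`VHIopt_1982.tif`, …), values rounded to six decimals, nodata −9999,
EPSG:4326 by default. `vhiopt run` writes `manifest.json` with a SHA-256 per
output; reruns on the same inputs are bit-identical.

## Layout

```
src/vhiopt/      core grids/cubes, GeoTIFF I/O, preprocessing, indices,
                 weight optimizer, detection, trends, synthetic scenes,
                 pipeline, CLI
examples/        five narrative scripts, one per capability
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance.py
docs/methods.md  methods note: model, parameters, generator design, limits
```
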