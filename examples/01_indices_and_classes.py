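"""Compute VCI, TCI and VHI from small NDVI/LST series and classify them.

Builds a three-pixel, five-year scene by hand, scales NDVI and LST into
their condition indices, mixes them with the equal-weight baseline, and
prints the drought class of each resulting VHI value.
"""

import numpy as np

from vhiopt import GridSpec, RasterCube, classify, compute_tci, compute_vci, compute_vhi

grid = GridSpec(n_rows=1, n_cols=3, origin_x=10.0, origin_y=45.0,
                pixel_size_x=0.05, pixel_size_y=0.05)
years = [2000, 2001, 2002, 2003, 2004]

# NDVI in [-1, 1]: pixel 0 greens up, pixel 1 browns down, pixel 2 oscillates
ndvi = np.array([
    [[0.20, 0.80, 0.50]],
    [[0.35, 0.65, 0.30]],
    [[0.50, 0.50, 0.55]],
    [[0.65, 0.35, 0.25]],
    [[0.80, 0.20, 0.60]],
])
# LST in kelvin: pixel 0 cools, pixel 1 heats, pixel 2 swings
lst = np.array([
    [[310.0, 290.0, 300.0]],
    [[305.0, 295.0, 308.0]],
    [[300.0, 300.0, 295.0]],
    [[295.0, 305.0, 309.0]],
    [[290.0, 310.0, 296.0]],
])

valid = np.ones(ndvi.shape, bool)
vci = compute_vci(RasterCube(grid, years, ndvi, valid.copy()))
tci = compute_tci(RasterCube(grid, years, lst, valid.copy()))
vhi = compute_vhi(vci, tci, 0.5)  # the equal-weight baseline index

print("year  pixel  VCI    TCI    VHI    class")
for k, year in enumerate(years):
    for j in range(3):
        v = vhi.values[k, 0, j]
        print(f"{year}  {j:5d}  {vci.values[k, 0, j]:5.1f}  "
              f"{tci.values[k, 0, j]:5.1f}  {v:5.1f}  {classify(v).name}")

# VCI/TCI are 0 at each pixel's worst observed year and 100 at its best;
# VHI averages them, and values at or below 40 indicate vegetation drought.
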