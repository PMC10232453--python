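"""Calibrate the per-pixel VCI contribution weight against a reference index.

Generates a synthetic scene whose true mixing weights are known (a gradient
from TCI-dominated to VCI-dominated across the grid), runs the 49-candidate
grid search against the noisy reference series, and summarizes how well the
weights are recovered and which component dominates where.
"""

import numpy as np

from vhiopt import (
    compute_vhi_opt, default_scenario, dominance_summary, generate_cubes,
    optimize_contribution,
)

scenario = default_scenario(seed=42)  # 32x32 pixels, 41 years, snr 10
vci, tci, ref, truth = generate_cubes(scenario)

cmap = optimize_contribution(vci, tci, ref)
err = np.abs(cmap.a_opt - truth.a_true)

print(f"pixels calibrated:        {int(cmap.valid.sum())} / {cmap.valid.size}")
print(f"median |a_opt - a_true|:  {np.median(err):.3f}")
print(f"within 0.04 of truth:     {100 * (err <= 0.04).mean():.1f}% of pixels")
print(f"median r at the optimum:  {np.median(cmap.r_max[cmap.valid]):.3f}")

f_tci, f_vci = dominance_summary(cmap)
print(f"TCI-dominated (a<0.5):    {100 * f_tci:.1f}%")
print(f"VCI-dominated (a>0.5):    {100 * f_vci:.1f}%")

vhi_opt = compute_vhi_opt(vci, tci, cmap)
print(f"VHI_opt range:            [{vhi_opt.values.min():.1f}, {vhi_opt.values.max():.1f}]")

# The weight search is exact on its 0.02 grid, so recovery error is dominated
# by reference noise; at snr 10 nearly every pixel lands within two grid
# steps of its true weight, and the dominance split mirrors the gradient.
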