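"""Derived depth indices: summed Vmax, cell-specific activity, and the
ratio of peptidolytic potential to modeled carbon oxidation.

Runs a full noiseless assay campaign (6 substrates x 5 depths), sums fitted
Vmax per depth, converts to per-cell activity with the anchored cell-count
profile, and normalizes against the 2-G model's oxidation-rate profile.
"""

import numpy as np

from sedpep.diagenesis import DiagenesisParams, solve_solutes
from sedpep.integration import bulk_density, cell_specific_vmax, vmax_to_oxidation_ratio
from sedpep.kinetics import CalibrationCurve, fit_assay, sum_vmax
from sedpep.profiles import DepthProfile
from sedpep.synthetic_data import (
    default_kinetic_truths,
    gen_core_tables,
    gen_saturation_assay,
)

calib = CalibrationCurve(slope=2.0)
fits = [fit_assay(gen_saturation_assay(gt), calib)
        for gt in default_kinetic_truths(noise_rel=0.0)]
summed = sum_vmax(fits, reference_depth=4.5)

print("depth (cm)   sum Vmax (umol g-1 h-1)   relative to 4.5 cm")
for z, v, r in zip(summed.profile.depths, summed.profile.values,
                   summed.normalized.values):
    print(f"{z:8.1f}   {v / 1e3:12.2f}              {100 * r:6.1f} %")

cells, _ = gen_core_tables(0, summed.profile.depths)
sum_umol = DepthProfile(summed.profile.depths, summed.profile.values / 1e3,
                        summed.profile.errors / 1e3)
cs = cell_specific_vmax(sum_umol, cells, rho_wet=bulk_density(0.8))
print(f"\ncell-specific activity: {cs.values.min():.0f} - {cs.values.max():.0f} "
      "amol AMC cell-1 h-1 across depths")
print("(roughly constant: hydrolysis potential scales with cell abundance)")

sol = solve_solutes(DiagenesisParams())
rc = DepthProfile(sol.grid, sol.r_c)
# the model domain starts at 4.5 cm, so the 1.5 cm horizon is dropped
import warnings
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ratio = vmax_to_oxidation_ratio(sum_umol, rc, reference_depth=4.5)
print(f"\nsum Vmax / OC oxidation at {ratio.depths[-1]:.1f} cm is "
      f"{ratio.values[-1]:.0f}x its value at 4.5 cm:")
print("enzyme potential declines far more slowly than carbon oxidation,")
print("so deep communities maintain enzymes that return hydrolysate slowly.")
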