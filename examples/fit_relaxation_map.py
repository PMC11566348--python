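"""Fit a T1rho map from a forward-simulated spin-lock series and threshold it.

Builds a small annular cartilage phantom with known relaxation times, simulates the
four-spin-lock-time acquisition, refits every voxel and applies the 100 ms fluid
threshold.
"""

import numpy as np

from hiprelax import (
    CohortConfig,
    Contrast,
    apply_upper_threshold,
    fit_map,
    make_atlas,
    simulate_echo_series,
    simulate_truth_maps,
)

atlas = make_atlas(grid_shape=(2, 64, 64), head_center=(32, 32),
                   femur_radii=(11, 13), acetab_radii=(15, 17))
config = CohortConfig(seed=0, between_subject_sd_ms=2.0, spatial_sd_ms=1.5)
truth = simulate_truth_maps(atlas, config, participant=0)[Contrast.T1RHO]

series = simulate_echo_series(truth, noise_sd=2.0, seed=0)  # 2% of the S0=100 amplitude
fitted = fit_map(series, truth.valid)
fitted = apply_upper_threshold(fitted)  # 100 ms for T1rho

err = fitted.values[fitted.valid] - truth.values[fitted.valid]
print(f"voxels fitted            : {int(fitted.valid.sum())}")
print(f"truth mean T1rho         : {truth.values[truth.valid].mean():.2f} ms")
print(f"fitted mean T1rho        : {fitted.values[fitted.valid].mean():.2f} ms")
print(f"per-voxel RMSE           : {np.sqrt((err ** 2).mean()):.2f} ms")
# The RMSE (~1 ms at 2% signal noise) is the fitting noise a single acquisition
# carries into every downstream region mean.
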