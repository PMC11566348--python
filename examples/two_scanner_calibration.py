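"""Two-scanner calibration study: voxel-based relaxometry before and after Z-score
calibration.

The same 8-participant cohort (16 hips as paired units) is observed through two
scanners, the second with an affine bias (scale 1.1, offset +2 ms).  A voxel-wise
paired t-test quantifies the apparent difference; Z-score calibration re-expresses
the second scanner's maps in the first scanner's distribution and collapses it.
"""

from hiprelax import (
    CohortConfig,
    ScannerModel,
    VoxelStack,
    calibrate_map,
    compute_group_stats,
    paired_ttest_map,
    significant_fraction,
    simulate_two_scanner_study,
)

scanner1 = ScannerModel(1.0, 0.0, 1.5, "scanner1")
scanner2 = ScannerModel(1.1, 2.0, 1.5, "scanner2")  # affine inter-scanner bias
config = CohortConfig(n_participants=8, seed=0)

stack1, stack2, truth = simulate_two_scanner_study(config, scanner1, scanner2)
mask = truth["atlas"].femur_mask | truth["atlas"].acetab_mask

before = significant_fraction(paired_ttest_map(stack1, stack2), mask)

stats1 = compute_group_stats(stack1)  # per-voxel mean/SD across the 16 hips
stats2 = compute_group_stats(stack2)
calibrated = VoxelStack(
    [calibrate_map(m, stats2, stats1) for m in stack2.maps], list(stack2.subject_ids)
)
after = significant_fraction(paired_ttest_map(stack1, calibrated), mask)

print(f"significant voxels before calibration: {before:6.2f} %")
print(f"significant voxels after calibration : {after:6.2f} %")
# Before calibration nearly every voxel differs between scanners; after Z-score
# calibration the fraction drops to (or below) the 5% chance level of the test.
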