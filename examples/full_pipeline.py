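"""Run the staged pipeline end to end from a configuration object.

simulate -> fit -> threshold/slice-select -> subregions -> calibrate -> VBR,
with artifacts, provenance manifest and summary CSVs under the output directory.
Re-running with the same configuration is a no-op.
"""

import tempfile
from pathlib import Path

import pandas as pd

from hiprelax import PipelineConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "study"
config = PipelineConfig(
    out_dir=str(out), seed=0, n_participants=4,
    grid_shape=(4, 64, 64), head_center=(32.0, 32.0),
    femur_radii=(11.0, 13.0), acetab_radii=(15.0, 17.0),
)

manifest = run_pipeline(config)
print("stages run :", manifest["stages_run"])
print(pd.read_csv(out / "vbr_summary.csv").to_string(index=False))

manifest2 = run_pipeline(config)
print("re-run     :", manifest2["stages_run"], "(all stages up to date)")
# The summary shows the scanner bias detected before calibration (near-100%
# significant voxels) vanishing in the scanner1_vs_calibrated comparison.
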