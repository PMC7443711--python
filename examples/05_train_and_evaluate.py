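"""End-to-end smoke run: simulate a tiny dataset, train both networks,
and report per-vessel mean sO2 accuracy.

Uses the 'ci' preset (4 phantoms, 16^3 voxels) so it finishes in about a
minute; swap in 'mini' (~10 min) or 'scaled' (hours) for meaningful
accuracies.  The printed report compares three ways of reading vessel sO2
off the network outputs: through the segmentation network's confident
voxels, through the ground-truth vessel voxels, and via naive per-voxel
spectral unmixing of the raw images.
"""

import json
import tempfile
from pathlib import Path

from paovox import pipeline

workdir = Path(tempfile.mkdtemp(prefix="paovox_"))
cfg = pipeline.preset("ci", seed=0)
print(f"simulating {cfg.n_total} phantoms ({cfg.grid.shape} voxels) ...")
pipeline.generate_dataset(cfg, workdir / "data")

print("training networks A (sO2) and B (segmentation) ...")
result = pipeline.run_experiment(cfg, workdir / "data", workdir / "out")
print(json.dumps(result.to_dict(), indent=1))
print("mae_pp = mean |true - estimated| mean-vessel sO2 in percentage points;")
print("at this toy scale the numbers are dominated by under-training --")
print("see docs/methods.md for the problem sizes used in the test suite")
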