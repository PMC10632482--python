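"""End-to-end run: simulate a cohort, execute every stage, inspect the manifest.

Writes the synthetic inputs in the same CSV/YAML formats real data would
use, runs SCENITH profiling, quantile binning, Seahorse indices, supernatant
flux and the survival analysis, and prints the per-stage row counts from the
run manifest.
"""

import json
import tempfile
from pathlib import Path

from immunomet.pipeline import RunConfig, run, simulate_inputs
from immunomet.simulate import SyntheticCohortConfig

config = SyntheticCohortConfig(seed=13, cells_per_condition=500,
                               n_patients={"good": 6, "bad": 6})

with tempfile.TemporaryDirectory() as tmp:
    inputs = simulate_inputs(config, Path(tmp) / "inputs")
    run_config = RunConfig.from_dict({
        "seed": 13,
        "output_dir": str(Path(tmp) / "out"),
        "inputs": {kind: str(path) for kind, path in inputs.items()},
        "binning": {"markers": ["CD86", "HLA-DR"], "reference_group": "good"},
        "survival": {"endpoint": "OS", "covariates": ["mitochondrial_dependence"]},
    })
    manifest = run(run_config)
    print("per-stage results:")
    print(json.dumps(manifest["stages"], indent=2))
    out = Path(tmp) / "out"
    print("\nresult tables written:")
    for p in sorted(out.iterdir()):
        print(f"  {p.name}")
print(
    "\nRe-running with the same config and seed reproduces every table "
    "byte-for-byte; the manifest records the config hash and seed that "
    "make that reproduction possible."
)
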