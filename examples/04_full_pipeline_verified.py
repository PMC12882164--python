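"""End-to-end run verified against planted ground truth.

Simulates the default world, runs every stage (cascade, insertion origins,
interactomes), and scores the outputs against the truth manifest. On a
correct installation every stage reports precision = recall = 1.0.
"""

import tempfile
from pathlib import Path

from svprio.config import PipelineConfig
from svprio.pipeline import RunSpec, run_all
from svprio.synth import WorldParams, generate_world
from svprio.verify import verify_against_manifest

with tempfile.TemporaryDirectory() as tmp:
    world = Path(tmp) / "world"
    run_dir = Path(tmp) / "run"
    manifest = generate_world(WorldParams(rng_seed=17), world)
    run_all(RunSpec.from_world(world), run_dir, PipelineConfig())
    report = verify_against_manifest(run_dir, manifest)

print(report.summary())
print("\nPrecision counts planted truths among what the pipeline reported;"
      "\nrecall counts reported results among what was planted. 1.0/1.0 at"
      "\nevery stage means no planted candidate, exclusion reason, insertion"
      "\norigin, or convergence node was lost or invented.")
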