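"""Generate the synthetic study cohort.

Writes toy protein structures, catalytic-site trajectories drawn over a
shared set of conformational states, a proteome annotation table with known
curation ground truth, group-biased sequence sets, and the environment table
under results/cohort/.
"""

import sys

from thermadapt.pipeline import RunConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = RunConfig(seed=SEED, stages=("simulate",))
manifest = run_pipeline(cfg, "results/cohort")
outputs = manifest["stages"]["simulate"]["outputs"]
print(f"simulated cohort with seed {SEED}: {len(outputs)} files under results/cohort/simulate")
for rel in sorted(outputs):
    print(" ", rel)
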