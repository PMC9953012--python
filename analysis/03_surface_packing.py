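"""Surface, packing and dynamic-solvation analysis of the cohort.

For each synthetic protein: per-residue SASA and exposure, the packing ratio
(buried reference area / total SASA), the trajectory packing ratio with an
AR(1) parametric-bootstrap 95% CI, and the per-residue dynamic solvation
index D_i over the catalytic-site trajectory.
"""

import numpy as np
import pandas as pd

from thermadapt import surface as surf
from thermadapt.pipeline import RunConfig, stage_seed
from thermadapt.synthetic import gen_cohort

cfg = RunConfig(seed=1)
cohort = gen_cohort(cfg.n_proteins, cfg.n_frames, cfg.n_states, cfg.noise_sd,
                    seed=stage_seed(cfg.seed, "simulate"))

rows = []
for p in cohort:
    s = surf.sasa(p.structure)
    rsa = surf.relative_sasa(s, p.structure.residue_names)
    labels = surf.classify_exposure(rsa)
    pk = surf.packing_ratio(s, p.structure.residue_names)
    series = surf.sasa_series(p.trajectory)
    d = surf.dynamic_solvation(series)
    tp = surf.trajectory_packing(p.trajectory, seed=cfg.seed)
    rows.append(
        {
            "protein": p.protein_id,
            "T_K": p.environment.temperature,
            "packing_ratio": pk.ratio,
            "traj_packing_mean": tp.mean,
            "traj_packing_ci_lo": tp.ci[0],
            "traj_packing_ci_hi": tp.ci[1],
            "frac_exposed": float(np.mean(labels == "exposed")),
            "max_D": float(d.max()),
        }
    )
    print(
        f"{p.protein_id} (T={p.environment.temperature:.0f} K): structure packing {pk.ratio:.3f}, "
        f"catalytic-site trajectory packing {tp.mean:.3f} [{tp.ci[0]:.3f}, {tp.ci[1]:.3f}] "
        f"(negative: a 3-residue fragment exposes more area than its reference total), "
        f"{np.mean(labels == 'exposed'):.0%} exposed, max D_i {d.max():.2f}"
    )
df = pd.DataFrame(rows)
df.to_csv("results/surface_packing.tsv", sep="\t", index=False)
print("wrote results/surface_packing.tsv")
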