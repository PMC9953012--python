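# thermadapt

Comparative structural bioinformatics of thermally adapted D-Ala-D-Ala
carboxypeptidases (MEROPS S11/S12/S13 serine proteases) — the bacterial
penicillin-binding proteins that trim peptidoglycan stem peptides during cell
wall synthesis. Organisms from psychrophilic, mesophilic and thermophilic
habitats carry homologous copies of these enzymes, making them a natural
system for asking how protein sequence, packing, network cohesion and
active-site dynamics respond to environmental temperature.

The package implements the full analysis chain as a tested library with
numbered driver scripts, exercised end-to-end on synthetic data with known
ground truth:

* **Curation** — rule-based selection of putative non-membrane serine
  proteases from proteome annotation tables (GO/name boolean filter,
  membrane-region flagging with signal-peptide rescue in the first 70
  residues, configurable name blocklist).
* **Sequence analysis** — pairwise-deletion mismatch dissimilarity on an
  alignment, Ward (ward.D2-style) hierarchical clustering with cluster
  centroids, classical (Torgerson) MDS, amino-acid composition by residue
  and by class, and position frequency matrices with per-column information
  content (bits).
* **Surface analysis** — deterministic Shrake–Rupley SASA (probe 1.4 Å, 960
  points/atom, heavy atoms), relative solvent accessibility against
  reference areas `A_i` with exposure at RSA > 0.2, the packing ratio
  `(ΣA_i − Σs_i)/Σs_i`, trajectory packing means with AR(1)
  parametric-bootstrap 95% CIs, the dynamic solvation index
  `D_i = (max_t s_it − min_t s_it)/A_i`, and 3-state secondary structure.
* **Protein structure networks** — moiety nodes (backbone + chemically
  contiguous side-chain groups), contacts at ≤ 1.1× the summed van der
  Waals radii, degree and k-core cohesion, exposure/secondary-structure
  stratification, and OLS cohesion–temperature regression with Pearson ρ.
* **Interactions** — salt bridges (acidic O to basic N ≤ 3.2 Å, one count
  per residue pair), disulfides (SG–SG ≤ 2.3 Å, greedy matching), and a
  geometric hydrogen-bond census (D–A ≤ 3.5 Å, D–H···A ≥ 120°).
* **Active-site dynamics** — per-frame interatomic distance vectors over the
  21 heavy atoms of the catalytic S1/K/S2 triad, a six-layer random-ReLU /
  skip / PCA embedding to 25 dimensions (all trajectories jointly), k-means
  (75 restarts), state-count selection by posterior predictive Z-scores on
  the reduction in one-step-ahead Markov RMSE (Z > 2), Jeffreys-prior
  posteriors over occupancies, transition rates and waiting times, most
  central conformations, and a CART interpretation tree on raw distances.
* **Synthetic data** — ideal-geometry peptides, Markov-switching Gaussian
  catalytic-site trajectories with known state count / transition matrix /
  centroids, annotation tables with constructed curation ground truth, and
  group-biased sequence sets.

## Worked example

```python
import numpy as np
from thermadapt import statedyn
from thermadapt.synthetic import StateTrajectorySpec, gen_state_trajectory, make_site_centroids

# three trajectories over a shared set of 3 catalytic-site conformations
centroids = make_site_centroids(3, seed=42, separation=2.0)
P = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.05, 0.9]])
series = []
for s in range(3):
    spec = StateTrajectorySpec(3, 2000, P, centroids=centroids, noise_sd=0.25, seed=100 + s)
    traj, labels = gen_state_trajectory(spec)
    series.append(statedyn.catalytic_distance_series(traj, (0, 1, 2)))

X, slices = statedyn.stack_series(series)          # 6000 frames x 210 distances
model, embedded = statedyn.deep_rf_embed(X, seed=1)
state_model = statedyn.select_k(embedded, X, slices, k_range=range(2, 11), seed=1)
print(state_model.k)                                # 3
```

The selector prints `k = 3`: the Z-score for the RMSE reduction is ≈ 2992 at
k = 2 and ≈ 1071 at k = 3, then drops below 0 for k ≥ 4 — adding states
beyond the true three no longer improves one-step-ahead prediction of the
distance vectors, because within-state noise is memoryless. The recovered
assignment matches the generator's hidden state sequence exactly (adjusted
Rand index 1.0).

The numbered scripts under `analysis/` run the same machinery over a small
synthetic cohort (simulate → curate/cluster → surface/packing → PSN
cohesion → interactions → active-site states) and write their tables under
`results/`. A `thermadapt` CLI exposes each stage (`simulate`, `curate`,
`cluster-seqs`, `composition`, `surface`, `psn`, `interactions`, `states`,
`run-all`).

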