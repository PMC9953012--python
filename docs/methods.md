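# Methods

This note documents the models, conventions and numerical choices behind the
package, and what the synthetic-data experiments do and do not demonstrate.

## Structures, trajectories and conventions

Structures are parsed from PDB (first model; highest-occupancy altloc, ties
toward 'A'); amino-acid atoms only — solvent and ions are out of scope.
Hydrogens are retained at read time and flagged, and each stage declares its
own heavy-atom behaviour (SASA and PSN contacts are heavy-atom only; the
hydrogen-bond census uses explicit hydrogens where present and places ideal
amide hydrogens where absent). Residues are indexed 0-based and contiguous
internally; the original PDB `resSeq` is kept as metadata. Trajectories are
multi-model PDB (text fixtures) or DCD assumed to be in Ångströms; the
default frame interval is 20 ps, matching the convention of retaining 5000
frames from a 100 ns production run.

## Curation rules

A protein is kept when (a) a GO term contains "serine-type" and no GO term
contains "inhibitor", or (b) a generic peptidase GO term (id 0008233) is
present and the name contains "serine", or (c) the name contains "serine"
and one of protease/peptidase/proteinase. Matching is case-insensitive
substring matching on the annotation table as exported; GO descendants are
not expanded (the table is assumed pre-annotated, as UniProt exports are).
Membrane-flagged proteins are dropped unless every predicted membrane region
ends at or before residue 70 **and** a signal peptide is annotated — the
strict reading of an N-terminal membrane prediction being explained by a
signal sequence; a region straddling position 70 is therefore not
rescuable. The manual removal of Clp ATP-binding subunits is generalized to
a configurable name blocklist (default "ClpA", "ATP-binding subunit").

## Sequence dissimilarity and clustering

The dissimilarity between two aligned sequences is the mismatch fraction
over columns where neither has a gap (pairwise deletion); pairs with no
comparable columns get d = 1. This is the simplest measure consistent with
clustering on alignment-derived dissimilarity; no substitution-matrix
weighting is applied. Ward clustering is the ward.D2-style generalization
(Lance–Williams updates on squared dissimilarities, heights on the original
scale), delegated to scipy, whose `ward` linkage on a distance matrix is
exactly this variant; partitions were cross-checked against R's
`hclust(method = "ward.D2")`. Note that agglomerative Ward is greedy: its
k = 2 cut provably equals the exhaustive minimum-criterion bipartition on
clusterable matrices but need not on unstructured ones — the test suite
checks oracle equivalence on clusterable random matrices and reference-
implementation equivalence on unstructured ones. Cluster centroids minimize
the within-cluster dissimilarity row sum (ties to the lexicographically
smallest id). Classical MDS is Torgerson double-centering with negative
eigenvalues truncated to zero.

The composition class map (charged DEKR; uncharged polar STNQHYCW;
hydrophobic AVLIMFPG) is a convention, not a fact of the source data; a
Kyte–Doolittle-derived alternative ("KD > 0 plus P and G") ships as an
editable table. Position frequency matrices report per-column frequencies
over non-gap symbols and information content log2(20) − H in bits.

## SASA, packing, dynamic solvation

The SASA engine is Shrake–Rupley with a deterministic golden-spiral lattice
(default 960 points/atom, probe 1.4 Å, Bondi radii, heavy atoms only); it
is its own oracle across the package, with tests pinning it to the analytic
isolated-sphere area (< 1 %), a 10⁶-point Monte-Carlo two-sphere oracle
(< 0.5 %) and biotite's independent implementation. DSSP-style SASA values
would differ by a few percent; downstream metrics use only per-residue
totals, so the engine choice does not change any qualitative conclusion.
Reference areas A_i are the literature-standard theoretical maximum
accessible surface areas, shipped as an editable table. Exposure is strict:
RSA > 0.2.

The packing ratio is (ΣA_i − Σs_i)/Σs_i ≡ ΣA/Σs − 1, i.e. buried reference
area per unit of solvent-exposed area; negative buried area is permitted
(reported with a warning) since a fully extended chain can exceed the
reference total. Trajectory packing means carry a parametric-bootstrap 95 %
CI: an AR(1) model (lag-1 autocorrelation, innovation variance) is fit to
the per-frame ratio series, 1000 stationary replicate series are simulated,
and the 2.5/97.5 percentiles of replicate means are taken. AR(1) is the
simplest autocorrelation-aware model; series with longer memory would need
a higher-order fit. The dynamic solvation index is D_i =
(max_t s_it − min_t s_it)/A_i; it is 0 for a single frame and monotone
non-decreasing as frames accrue.

Secondary structure is the Kabsch–Sander assignment (via mdtraj's built-in
implementation) collapsed to three states (H,G,I → H; E,B → E; else C);
residues the assignment cannot cover are labeled C with a warning.

## Protein structure networks

Nodes are chemical moieties: one backbone group per residue (N, CA, C, O,
OXT) plus chemically contiguous side-chain groups from a shipped, editable
table (e.g. Lys CB–CG–CD and CE–NZ; Glu CB–CG and the carboxylate). This is
the documented fallback convention for moiety-level networks; the table can
be replaced without code changes. Two moieties are adjacent when any heavy
atom pair lies within 1.1× the sum of Bondi radii, compared with "≤" at
exactly the threshold. Edges between moieties of the same residue are
included by default (the contact rule is applied uniformly) and can be
disabled. Core numbers are standard peeling; cohesion summaries stratify by
residue exposure and secondary structure, moieties inheriting their
residue's labels. Cohesion–temperature association is OLS with Pearson ρ, a
two-sided t-test and pointwise 95 % confidence bands; it requires at least
three proteins and non-degenerate temperatures.

## Interaction censuses

Salt bridges pair a side-chain carboxylate oxygen (Asp OD1/OD2, Glu
OE1/OE2) with a basic side-chain nitrogen (Lys NZ, Arg NH1/NH2/NE) within
3.2 Å — the cited detection tool's default — counting each residue pair
once; histidine counts as basic only when explicitly marked protonated.
Disulfides are Cys SG–SG pairs within 2.3 Å matched greedily nearest-first.
The hydrogen-bond criterion is geometric (donor–acceptor ≤ 3.5 Å, D–H···A
≥ 120°, same-residue pairs excluded) since no energy-based criterion is
defined for this analysis; thresholds are configurable, and the census
matches an independent library evaluation of the same criterion exactly on
the helix fixture. Censuses default to single structures; trajectory frames
can be censused individually.

## Active-site conformational states

Input is the vectorized strict upper triangle of the frame-wise interatomic
distance matrix over the heavy atoms of the catalytic triad, in fixed order
(S1 atoms, then K, then S2; file order within a residue) — 210 distances
for the canonical Ser(6)/Lys(9)/Ser(6) site. All trajectories are embedded
jointly. Each of six layers appends an intercept column, projects onto 500
random ReLU functions whose weight vectors are unit-norm Gaussian draws
(uniform on the sphere), concatenates a skip copy of its input, and prunes
to 25 features by column-centered PCA (covariance eigendecomposition, no
whitening, sign fixed by making the largest-absolute loading positive). One
seed drives all layers; the fitted model embeds new frames independently of
the data used to fit it.

States come from Lloyd k-means (75 random restarts, 100 iterations, best
within-cluster sum of squares; scikit-learn's empty-cluster relocation is
used instead of redrawing centers — with 75 restarts the distinction has
never mattered in our experiments). The state count is chosen by a total
Markov-error argument operationalized as one-step-ahead predictive RMSE on
the original distance scale: within each trajectory the Jeffreys
(Dirichlet-½) posterior over transitions is estimated, frame t+1 is
predicted as the posterior-weighted mixture of state centroids, and the
reduction Δ(k) = RMSE(k−1) − RMSE(k), averaged over trajectories, is
evaluated over 1000 posterior transition-matrix draws; Z(k) = mean/sd, and
the chosen k is the largest candidate with Z > 2 (candidates with empty
states are rejected; if none qualifies the model falls back to k = 1 with a
warning). This one-step predictive operationalization, and the use of
posterior-predictive rather than between-trajectory variance in Z, are the
pipeline's principal interpretive decisions; both variance conventions are
simple to swap. The mechanism that makes the selector consistent on the
synthetic model is that within-state noise is memoryless: splitting a true
state leaves one-step predictions essentially unchanged, so Δ(k) beyond the
true k has mean ≈ 0 under posterior draws.

Occupancy and transition posteriors use Jeffreys priors: posterior mean
p_ij = (n_ij + ½)/(n_i· + k/2). Waiting times use the geometric holding
interpretation frame_interval / p_ij, reported in ns, with 95 % intervals
from the Beta marginal quantiles of p_ij — wide when a transition is
unobserved, as expected. The most central conformation of a state is the
member frame nearest the state mean in distance space (ties to the earliest
frame). The interpretation tree is CART with Gini impurity on the raw
distances (depth ≤ 3, cost-complexity pruning at 0.001, splits rendered as
"distance ≥ threshold"); 150 frames are held out to report an out-of-sample
accuracy when enough data are available.

## Synthetic data: what it emulates and what it does not

The conformational-trajectory generator is a hidden Markov chain over k
site conformations observed through isotropic Gaussian coordinate noise;
states differ by internal deformation (not rigid motion), so their distance
vectors are genuinely distinct, and "well-separated" fixtures keep pairwise
centroid RMSD above 4× the noise sd (defaults: noise 0.25 Å, separation
2 Å — comfortably distinct conformations at sub-Å thermal jitter). Peptide
fixtures are ideal-geometry backbones (helix φ = −57°, ψ = −47°; extended
φ = −135°, ψ = 135°; "separated" places residues ≥ 20 Å apart). Annotation
tables plant decoys violating exactly one curation rule each. The cohort
generator assigns temperatures across 275–350 K and draws per-protein
sticky transition matrices over a shared state set.

These fixtures validate the machinery — recovery of planted states,
curation rules, oracle-exact geometry — not biological conclusions: real
MD trajectories have correlated, anisotropic, multiscale fluctuations; real
proteins have side chains, heterogeneous composition, and real secondary
structure; and composition/cohesion trends across real thermal groups
cannot be inferred from these generators. Passing tests show the
measurement chain is correct, deterministic and consistent, nothing more.

Problem sizes in the test-suite experiments (e.g. 5000-frame, 3-trajectory
state-recovery replicates; 500-frame end-to-end cohorts; 100-table curation
sweeps) were chosen as the smallest sizes at which the statistical checks
are stable.

## Determinism

Every stochastic component is seeded; a single master seed fans out to
per-stage seeds by stable SHA-256 hashing of stage names. Pipeline manifests
contain no timestamps, and reruns with an unchanged configuration are
byte-identical; up-to-date stages are skipped on partial reruns. Known
numerical caveats: PCA sign conventions are fixed, k-means ties follow
scikit-learn's deterministic behaviour at a fixed random state, and PDB
round-trips are exact to the format's 3-decimal coordinate precision.

## Known limitations

* The dissimilarity measure ignores substitution similarity; closely related
  groups separated only by conservative substitutions will look more distant
  than a BLOSUM-weighted measure would report.
* DSSP-exact SASA values are out of scope; only Shrake–Rupley totals are
  produced.
* The moiety table is a convention; published moiety definitions can be
  dropped in via the data file.
* The Markov waiting-time definition is the geometric holding time; mean
  first-passage times under the full chain are not computed.
* The AR(1) bootstrap under-covers for series whose autocorrelation decays
  much more slowly than geometrically.
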