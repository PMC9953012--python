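"""Conformational-state analysis of catalytic-site dynamics.

Pipeline: per-frame interatomic distance vectors over the heavy atoms of the
catalytic (S1, K, S2) residues -> deep random-feature embedding (six stacked
layers of 500 random ReLU projections with an intercept feature, a skip copy
of the inputs, and PCA pruning to 25 dimensions) -> k-means clustering ->
selection of the state count k by the reduction in one-step-ahead Markov
predictive RMSE (posterior predictive Z-score > 2) -> Jeffreys-prior
posteriors over occupancies, transition rates and waiting times -> most
central conformations and a CART interpretation tree on the raw distances.

All trajectories are embedded jointly into the same space so states are
comparable across proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .structures import Trajectory

# ---------------------------------------------------------------------------
# Distance series
# ---------------------------------------------------------------------------

ROLES = ("S1", "K", "S2")


@dataclass
class DistanceVectorSeries:
    """Frame-wise vectorized interatomic distance matrices (strict upper triangle)."""

    trajectory_id: str
    times: np.ndarray  # ps
    atom_labels: list[str]  # e.g. "OG.S1"
    pair_labels: list[str]  # e.g. "OG.S1.O.S2"
    vectors: np.ndarray  # (n_frames, m)

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]


def catalytic_distance_series(
    traj: Trajectory, catalytic_residues: Sequence[int]
) -> DistanceVectorSeries:
    """All pairwise heavy-atom distances among the three catalytic residues.

    Atom order is fixed: S1 atoms, then K, then S2, each in topology file
    order; the vector is the strict upper triangle of the distance matrix.
    """
    if len(catalytic_residues) != 3:
        raise ValueError("catalytic_residues must be the (S1, K, S2) residue indices")
    top = traj.topology
    heavy_mask = top.is_heavy
    atom_idx: list[int] = []
    atom_labels: list[str] = []
    for role, ridx in zip(ROLES, catalytic_residues):
        sel = np.where((top.residue_index == ridx) & heavy_mask)[0]
        if len(sel) == 0:
            raise ValueError(f"residue index {ridx} ({role}) not present in topology")
        atom_idx.extend(int(i) for i in sel)
        atom_labels.extend(f"{top.name[i]}.{role}" for i in sel)
    coords = traj.coords[:, atom_idx, :]
    iu, ju = np.triu_indices(len(atom_idx), k=1)
    diffs = coords[:, iu, :] - coords[:, ju, :]
    vectors = np.sqrt(np.sum(diffs**2, axis=2))
    pair_labels = [f"{atom_labels[i]}.{atom_labels[j]}" for i, j in zip(iu, ju)]
    return DistanceVectorSeries(
        trajectory_id=top.source_id,
        times=traj.times,
        atom_labels=atom_labels,
        pair_labels=pair_labels,
        vectors=vectors,
    )


def stack_series(series: Sequence[DistanceVectorSeries]) -> tuple[np.ndarray, list[slice]]:
    """Concatenate frame vectors from several trajectories; returns (X, slices)."""
    ms = {s.m for s in series}
    if len(ms) != 1:
        raise ValueError("all trajectories must share the same distance dimensionality")
    X = np.vstack([s.vectors for s in series])
    slices = []
    start = 0
    for s in series:
        slices.append(slice(start, start + s.n_frames))
        start += s.n_frames
    return X, slices


# ---------------------------------------------------------------------------
# Deep random-feature embedding
# ---------------------------------------------------------------------------


@dataclass
class _Layer:
    weights: np.ndarray  # (n_rf, m+1) unit-norm rows
    mean: np.ndarray  # column means of [F, Z]
    components: np.ndarray  # (n_pca, n_features) orthonormal loadings


@dataclass
class EmbeddingModel:
    layers: list[_Layer]
    seed: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float)
        for layer in self.layers:
            Z_aug = np.hstack([Z, np.ones((Z.shape[0], 1))])
            F = np.maximum(Z_aug @ layer.weights.T, 0.0)
            full = np.hstack([F, Z])
            Z = (full - layer.mean) @ layer.components.T
        return Z


def _fit_pca(X: np.ndarray, n_pca: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered PCA via the feature covariance; deterministic sign."""
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:n_pca]
    comp = eigvec[:, order].T  # (n_pca, n_features)
    # sign convention: largest-absolute loading positive
    for r in range(comp.shape[0]):
        j = int(np.argmax(np.abs(comp[r])))
        if comp[r, j] < 0:
            comp[r] = -comp[r]
    return mean, comp


def deep_rf_embed(
    X: np.ndarray,
    n_rf: int = 500,
    n_pca: int = 25,
    n_layers: int = 6,
    seed: int = 0,
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit the stacked random-ReLU / skip / PCA embedding on all frames jointly."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_pca:
        raise ValueError(f"need at least n_pca={n_pca} frames, got {n}")
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    Z = X
    for _ in range(n_layers):
        m = Z.shape[1]
        W = rng.normal(size=(n_rf, m + 1))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        Z_aug = np.hstack([Z, np.ones((n, 1))])
        F = np.maximum(Z_aug @ W.T, 0.0)
        full = np.hstack([F, Z])
        mean, comp = _fit_pca(full, n_pca)
        layers.append(_Layer(weights=W, mean=mean, components=comp))
        Z = (full - mean) @ comp.T
    return EmbeddingModel(layers=layers, seed=seed), Z


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def kmeans_states(
    embedded: np.ndarray,
    k: int,
    restarts: int = 75,
    iters: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means, random data-point-free init, best of ``restarts`` runs."""
    n = embedded.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of frames n={n}")
    if k == 1:
        centroid = embedded.mean(axis=0, keepdims=True)
        return np.zeros(n, dtype=int), centroid
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        max_iter=iters,
        algorithm="lloyd",
        random_state=seed % (2**32),
    )
    labels = km.fit_predict(embedded)
    return labels.astype(int), km.cluster_centers_


def state_centroids(vectors: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Mean distance-space vector of each state's member frames."""
    m = vectors.shape[1]
    out = np.zeros((k, m))
    for s in range(k):
        mask = labels == s
        if mask.any():
            out[s] = vectors[mask].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Markov posterior machinery (Jeffreys priors)
# ---------------------------------------------------------------------------


def transition_counts(labels: np.ndarray, k: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=0) < 0 or (len(labels) and labels.max() >= k):
        raise ValueError("labels out of range 0..k-1")
    counts = np.zeros((k, k))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    return counts


def jeffreys_posterior_mean(counts: np.ndarray) -> np.ndarray:
    """Posterior mean transition matrix under row-wise Dirichlet(1/2,...,1/2)."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    return (counts + 0.5) / (counts.sum(axis=1, keepdims=True) + k / 2.0)


@dataclass
class TrajectoryPosterior:
    trajectory_id: str
    counts: np.ndarray
    transition_mean: np.ndarray
    occupancy_mean: np.ndarray
    waiting_time_mean: np.ndarray  # ns, (k, k)
    waiting_time_interval: np.ndarray  # ns, (k, k, 2) [low, high]


@dataclass
class MarkovPosterior:
    k: int
    frame_interval: float  # ps
    per_trajectory: list[TrajectoryPosterior]


def markov_posterior(
    labels_per_traj: Sequence[np.ndarray],
    k: int,
    frame_interval: float = 20.0,
    trajectory_ids: Sequence[str] | None = None,
) -> MarkovPosterior:
    """Jeffreys posteriors over occupancy, transitions and waiting times.

    The waiting time for the i->j transition is the geometric holding time
    ``frame_interval / p_ij`` (reported in ns); its 95% interval comes from
    the Beta marginal quantiles of p_ij.
    """
    ids = list(trajectory_ids) if trajectory_ids else [f"traj{i}" for i in range(len(labels_per_traj))]
    out = []
    for tid, labels in zip(ids, labels_per_traj):
        counts = transition_counts(np.asarray(labels), k)
        P = jeffreys_posterior_mean(counts)
        occ_counts = np.bincount(np.asarray(labels, dtype=int), minlength=k).astype(float)
        occupancy = (occ_counts + 0.5) / (occ_counts.sum() + k / 2.0)
        n_i = counts.sum(axis=1, keepdims=True)
        a = counts + 0.5
        b = n_i - counts + 0.5 * (k - 1)
        q_lo = stats.beta.ppf(0.025, a, b)
        q_hi = stats.beta.ppf(0.975, a, b)
        dt_ns = frame_interval / 1000.0
        wait_mean = dt_ns / P
        wait_iv = np.stack([dt_ns / q_hi, dt_ns / q_lo], axis=-1)
        out.append(
            TrajectoryPosterior(
                trajectory_id=tid,
                counts=counts,
                transition_mean=P,
                occupancy_mean=occupancy,
                waiting_time_mean=wait_mean,
                waiting_time_interval=wait_iv,
            )
        )
    return MarkovPosterior(k=k, frame_interval=frame_interval, per_trajectory=out)


# ---------------------------------------------------------------------------
# State-count selection by total Markov (one-step predictive) error
# ---------------------------------------------------------------------------


@dataclass
class _PredStats:
    """Sufficient statistics for one-step-ahead SSE as a function of P."""

    n_i: np.ndarray  # (k,) frames in state i with a successor
    S: np.ndarray  # (k, m) sum of successor vectors
    Q: np.ndarray  # (k,) sum of squared norms of successors
    C: np.ndarray  # (k, m) state centroids in distance space
    counts: np.ndarray  # (k, k) transition counts
    T: int  # frames
    m: int

    def rmse(self, P: np.ndarray) -> float:
        mu = P @ self.C  # (k, m) predicted next vector given current state
        sse = float(
            np.sum(self.n_i * np.sum(mu**2, axis=1))
            - 2.0 * np.sum(mu * self.S)
            + np.sum(self.Q)
        )
        return np.sqrt(max(sse, 0.0) / ((self.T - 1) * self.m))


def _pred_stats(vectors: np.ndarray, labels: np.ndarray, k: int) -> _PredStats:
    T, m = vectors.shape
    cur = labels[:-1]
    nxt = vectors[1:]
    n_i = np.bincount(cur, minlength=k).astype(float)
    S = np.zeros((k, m))
    np.add.at(S, cur, nxt)
    Q = np.zeros(k)
    np.add.at(Q, cur, np.sum(nxt**2, axis=1))
    return _PredStats(
        n_i=n_i,
        S=S,
        Q=Q,
        C=state_centroids(vectors, labels, k),
        counts=transition_counts(labels, k),
        T=T,
        m=m,
    )


def _draw_rmses(
    stats_per_traj: list[_PredStats], n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean-over-trajectory RMSE for each posterior transition-matrix draw."""
    out = np.zeros(n_draws)
    for st in stats_per_traj:
        k = st.counts.shape[0]
        alphas = st.counts + 0.5
        draws = np.empty((n_draws, k, k))
        for i in range(k):
            draws[:, i, :] = rng.dirichlet(alphas[i], size=n_draws)
        rmses = np.array([st.rmse(draws[d]) for d in range(n_draws)])
        out += rmses
    return out / len(stats_per_traj)


@dataclass
class StateModel:
    k: int
    assignment: np.ndarray  # labels over all stacked frames
    assignment_per_traj: list[np.ndarray]
    centroids_distance: np.ndarray  # (k, m) in original distance space
    centroids_embedded: np.ndarray  # (k, n_pca)
    diagnostics: list[dict] = field(default_factory=list)  # per-k rmse/delta/z


def select_k(
    embedded: np.ndarray,
    vectors: np.ndarray,
    boundaries: Sequence[slice],
    k_range: Sequence[int] = tuple(range(2, 11)),
    z_threshold: float = 2.0,
    n_draws: int = 1000,
    restarts: int = 75,
    iters: int = 100,
    seed: int = 0,
) -> StateModel:
    """Choose the state count by posterior predictive Z-scores of RMSE reduction.

    For each candidate k the frames are clustered jointly; within each
    trajectory a Jeffreys posterior over transitions is estimated and the
    next frame's distance vector is predicted as the posterior-weighted
    centroid mixture. Delta(k) = RMSE(k-1) - RMSE(k) is evaluated over
    ``n_draws`` posterior transition-matrix draws; Z(k) = mean/sd. The
    chosen k is the largest candidate with Z > ``z_threshold`` (k with empty
    states are rejected); if none qualifies, k=1 with a warning.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    n = embedded.shape[0]
    if len(boundaries) < 2 and n < 100:
        raise ValueError("need >= 2 trajectories or one with >= 100 frames")
    rng = np.random.default_rng(seed)
    ks = [1] + [k for k in k_range if k > 1]

    labelings: dict[int, np.ndarray] = {}
    emb_centroids: dict[int, np.ndarray] = {}
    rmse_draws: dict[int, np.ndarray] = {}
    rmse_point: dict[int, float] = {}
    valid: dict[int, bool] = {}
    for k in ks:
        labels, centers = kmeans_states(embedded, k, restarts, iters, seed=seed + k)
        labelings[k] = labels
        emb_centroids[k] = centers
        valid[k] = len(np.unique(labels)) == k
        stats_pt = [_pred_stats(vectors[sl], labels[sl], k) for sl in boundaries]
        rmse_point[k] = float(
            np.mean([st.rmse(jeffreys_posterior_mean(st.counts)) for st in stats_pt])
        )
        rmse_draws[k] = _draw_rmses(stats_pt, n_draws, rng)

    diagnostics = []
    z_by_k: dict[int, float] = {}
    prev = 1
    for k in ks[1:]:
        delta = rmse_draws[prev] - rmse_draws[k]
        sd = float(delta.std(ddof=1))
        mean = float(delta.mean())
        z = mean / sd if sd > 0 else (np.inf if mean > 0 else -np.inf)
        z_by_k[k] = z
        diagnostics.append(
            {
                "k": k,
                "rmse": rmse_point[k],
                "rmse_prev": rmse_point[prev],
                "delta_mean": mean,
                "delta_sd": sd,
                "z": z,
                "occupied": int(len(np.unique(labelings[k]))),
            }
        )
        prev = k

    passing = [k for k in ks[1:] if z_by_k[k] > z_threshold and valid[k]]
    if passing:
        chosen = max(passing)
    else:
        warnings.warn("no candidate k exceeded the Z threshold; falling back to k=1")
        chosen = 1
    labels = labelings[chosen]
    return StateModel(
        k=chosen,
        assignment=labels,
        assignment_per_traj=[labels[sl] for sl in boundaries],
        centroids_distance=state_centroids(vectors, labels, chosen),
        centroids_embedded=emb_centroids[chosen],
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Central conformations
# ---------------------------------------------------------------------------


def central_conformation(vectors: np.ndarray, labels: np.ndarray) -> dict[int, int]:
    """Per state, the member frame closest (Euclidean, original distance space)
    to the state mean; ties resolve to the earliest frame."""
    out = {}
    for s in sorted(set(int(x) for x in labels)):
        idx = np.where(labels == s)[0]
        if len(idx) == 0:  # pragma: no cover
            warnings.warn(f"state {s} empty; skipped")
            continue
        mean = vectors[idx].mean(axis=0)
        d = np.linalg.norm(vectors[idx] - mean, axis=1)
        out[s] = int(idx[np.argmin(d)])
    return out


# ---------------------------------------------------------------------------
# Interpretation tree
# ---------------------------------------------------------------------------


@dataclass
class TreeModel:
    """CART on raw heavy-atom distances, annotated for interpretation."""

    tree: object  # fitted sklearn DecisionTreeClassifier
    pair_labels: list[str]
    classes: np.ndarray
    heldout_accuracy: float | None = None

    @property
    def root_feature(self) -> str | None:
        t = self.tree.tree_
        if t.node_count == 0 or t.feature[0] < 0:
            return None
        return self.pair_labels[t.feature[0]]

    @property
    def root_threshold(self) -> float | None:
        t = self.tree.tree_
        if t.node_count == 0 or t.feature[0] < 0:
            return None
        return float(t.threshold[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.tree.predict(X) == y))

    def render(self) -> str:
        """Text rendering: one node per line with dominant state, per-state
        fractions, and the fraction of the data below the node."""
        t = self.tree.tree_
        n_total = t.weighted_n_node_samples[0]
        lines: list[str] = []

        def recurse(node: int, depth: int, label: str) -> None:
            counts = t.value[node][0] * t.weighted_n_node_samples[node] / max(
                t.value[node][0].sum(), 1e-12
            )
            fracs = t.value[node][0] / max(t.value[node][0].sum(), 1e-12)
            dominant = self.classes[int(np.argmax(fracs))]
            frac_data = t.weighted_n_node_samples[node] / n_total
            head = f"{'  ' * depth}{label}state {dominant} | " + " ".join(
                f"{c}:{f:.2f}" for c, f in zip(self.classes, fracs)
            ) + f" | data {frac_data:.2f}"
            lines.append(head)
            if t.feature[node] >= 0:
                name = self.pair_labels[t.feature[node]]
                thr = t.threshold[node]
                recurse(t.children_right[node], depth + 1, f"[{name} >= {thr:.3g} A] ")
                recurse(t.children_left[node], depth + 1, f"[{name} < {thr:.3g} A] ")

        recurse(0, 0, "")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        t = self.tree.tree_

        def node(i: int) -> dict:
            fracs = (t.value[i][0] / max(t.value[i][0].sum(), 1e-12)).tolist()
            d = {
                "dominant_state": int(self.classes[int(np.argmax(fracs))]),
                "state_fractions": fracs,
                "data_fraction": float(t.weighted_n_node_samples[i] / t.weighted_n_node_samples[0]),
            }
            if t.feature[i] >= 0:
                d["distance"] = self.pair_labels[t.feature[i]]
                d["threshold"] = float(t.threshold[i])
                d["ge"] = node(t.children_right[i])
                d["lt"] = node(t.children_left[i])
            return d

        return node(0)


def state_tree(
    vectors: np.ndarray,
    labels: np.ndarray,
    pair_labels: Sequence[str],
    max_depth: int = 3,
    cp: float = 0.001,
    xval: int = 150,
    seed: int = 0,
) -> TreeModel:
    """CART (Gini) predicting state membership from raw distances.

    ``cp`` is the complexity parameter used for cost-complexity pruning;
    ``xval`` frames are held out (when available) to estimate out-of-sample
    accuracy.
    """
    from sklearn.tree import DecisionTreeClassifier

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 states to fit a tree")
    n = vectors.shape[0]
    rng = np.random.default_rng(seed)
    heldout_acc = None
    fit_X, fit_y = vectors, labels
    if 0 < xval < n // 2:
        perm = rng.permutation(n)
        hold, train = perm[:xval], perm[xval:]
        if len(np.unique(labels[train])) == len(np.unique(labels)):
            probe = DecisionTreeClassifier(
                criterion="gini", max_depth=max_depth, ccp_alpha=cp, random_state=seed % 2**32
            ).fit(vectors[train], labels[train])
            heldout_acc = float(np.mean(probe.predict(vectors[hold]) == labels[hold]))
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, ccp_alpha=cp, random_state=seed % 2**32
    ).fit(fit_X, fit_y)
    return TreeModel(
        tree=tree,
        pair_labels=list(pair_labels),
        classes=tree.classes_,
        heldout_accuracy=heldout_acc,
    )
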