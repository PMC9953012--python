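import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from thermadapt import statedyn
from thermadapt.statedyn import (
    catalytic_distance_series,
    central_conformation,
    deep_rf_embed,
    jeffreys_posterior_mean,
    kmeans_states,
    markov_posterior,
    select_k,
    stack_series,
    state_centroids,
    state_tree,
    transition_counts,
)
from thermadapt.synthetic import (
    StateTrajectorySpec,
    gen_state_trajectory,
    make_site_centroids,
)


class TestDistanceSeries:
    def test_21_atoms_give_210_distances(self, two_state_series):
        series, _ = two_state_series
        assert series.m == 210
        assert len(series.atom_labels) == 21
        assert series.atom_labels[0].endswith(".S1")
        assert series.atom_labels[-1].endswith(".S2")

    def test_single_frame_trajectory(self):
        spec = StateTrajectorySpec(1, 1, np.array([[1.0]]), seed=0)
        traj, _ = gen_state_trajectory(spec)
        series = catalytic_distance_series(traj, (0, 1, 2))
        assert series.vectors.shape == (1, 210)

    def test_coincident_atoms_give_zero_distance(self):
        spec = StateTrajectorySpec(1, 1, np.array([[1.0]]), noise_sd=0.0, seed=0)
        traj, _ = gen_state_trajectory(spec)
        traj.coords[0, 1] = traj.coords[0, 0]
        series = catalytic_distance_series(traj, (0, 1, 2))
        assert series.vectors[0, 0] == 0.0

    def test_missing_residue_rejected(self, two_state_series):
        spec = StateTrajectorySpec(1, 2, np.array([[1.0]]), seed=0)
        traj, _ = gen_state_trajectory(spec)
        with pytest.raises(ValueError, match="residue index 5"):
            catalytic_distance_series(traj, (0, 1, 5))

    def test_distances_match_direct_norms(self):
        spec = StateTrajectorySpec(1, 3, np.array([[1.0]]), seed=1)
        traj, _ = gen_state_trajectory(spec)
        series = catalytic_distance_series(traj, (0, 1, 2))
        d01 = np.linalg.norm(traj.coords[:, 0] - traj.coords[:, 1], axis=1)
        assert np.allclose(series.vectors[:, 0], d01)


class TestEmbedding:
    def test_duplicate_rows_embed_identically(self, two_state_series):
        series, _ = two_state_series
        X = np.vstack([series.vectors[:50], series.vectors[:1]])
        _, emb = deep_rf_embed(X, seed=0)
        assert np.allclose(emb[0], emb[-1])

    def test_permuting_frames_permutes_embedding(self, two_state_series):
        series, _ = two_state_series
        X = series.vectors[:200]
        _, emb = deep_rf_embed(X, seed=5)
        perm = np.random.default_rng(0).permutation(len(X))
        _, emb_p = deep_rf_embed(X[perm], seed=5)
        assert np.allclose(emb_p[np.argsort(perm)], emb, atol=1e-8)

    def test_transform_reproduces_training_embedding(self, two_state_series):
        series, _ = two_state_series
        model, emb = deep_rf_embed(series.vectors, seed=1)
        assert np.allclose(model.transform(series.vectors), emb, atol=1e-10)

    def test_separated_states_remain_separable(self, two_state_series):
        series, labels = two_state_series
        _, emb = deep_rf_embed(series.vectors, seed=5)
        assert silhouette_score(emb, labels) >= 0.6
        pred, _ = kmeans_states(emb, 2, restarts=10, seed=0)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            deep_rf_embed(np.zeros((10, 210)), n_pca=25)


class TestKMeans:
    def test_k1_centroid_is_grand_mean(self, two_state_series):
        series, _ = two_state_series
        labels, centers = kmeans_states(series.vectors[:100], 1)
        assert np.allclose(centers[0], series.vectors[:100].mean(axis=0))

    def test_two_blob_recovery(self, two_state_series):
        series, labels = two_state_series
        _, emb = deep_rf_embed(series.vectors, seed=2)
        pred, _ = kmeans_states(emb, 2, restarts=20, seed=1)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_same_seed_identical_assignment(self, two_state_series):
        series, _ = two_state_series
        a1, _ = kmeans_states(series.vectors, 3, restarts=5, seed=9)
        a2, _ = kmeans_states(series.vectors, 3, restarts=5, seed=9)
        assert np.array_equal(a1, a2)

    def test_k_exceeding_frames_rejected(self):
        with pytest.raises(ValueError):
            kmeans_states(np.zeros((5, 3)), 6)


class TestMarkovPosterior:
    def test_posterior_mean_from_counts(self):
        P = jeffreys_posterior_mean(np.array([[3.0, 1.0], [2.0, 4.0]]))
        assert np.allclose(P[0], [0.7, 0.3])
        assert np.allclose(P[1], [2.5 / 7, 4.5 / 7])

    def test_zero_count_row_gives_uniform(self):
        P = jeffreys_posterior_mean(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(P[0], [0.5, 0.5])

    def test_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(5, 5)).astype(float)
        P = jeffreys_posterior_mean(counts)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_consistency_on_long_chain(self):
        P = np.array([[0.85, 0.1, 0.05], [0.05, 0.9, 0.05], [0.1, 0.1, 0.8]])
        rng = np.random.default_rng(11)
        n = 100_000
        labels = np.empty(n, dtype=int)
        labels[0] = 0
        cum = P.cumsum(axis=1)
        u = rng.random(n)
        for t in range(1, n):
            labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])
        post = markov_posterior([labels], 3)
        est = post.per_trajectory[0].transition_mean
        assert np.max(np.abs(est - P)) < 0.01

    def test_waiting_time_definition_and_units(self):
        labels = np.array([0, 0, 1, 0, 0, 1])
        post = markov_posterior([labels], 2, frame_interval=20.0)
        tp = post.per_trajectory[0]
        # p_01 = (2 + 0.5) / (4 + 1) = 0.5 -> waiting time 20 ps / 0.5 = 40 ps = 0.04 ns
        assert tp.transition_mean[0, 1] == pytest.approx(0.5)
        assert tp.waiting_time_mean[0, 1] == pytest.approx(0.04)
        lo, hi = tp.waiting_time_interval[0, 1]
        assert lo < tp.waiting_time_mean[0, 1] < hi

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            transition_counts(np.array([0, 2, 1]), 2)


class TestSelectK:
    def test_true_k_recovered_on_joint_fixture(self, shared_centroids3):
        P = np.full((3, 3), 0.05)
        np.fill_diagonal(P, 0.9)
        series_list, truths = [], []
        for s in range(2):
            spec = StateTrajectorySpec(
                3, 800, P, centroids=shared_centroids3, noise_sd=0.25, seed=50 + s
            )
            traj, lab = gen_state_trajectory(spec)
            series_list.append(catalytic_distance_series(traj, (0, 1, 2)))
            truths.append(lab)
        X, slices = stack_series(series_list)
        _, emb = deep_rf_embed(X, seed=1)
        model = select_k(emb, X, slices, k_range=range(2, 6), restarts=20, seed=1)
        assert model.k == 3
        assert adjusted_rand_score(np.concatenate(truths), model.assignment) >= 0.95

    def test_single_state_null_falls_back_to_k1(self):
        spec = StateTrajectorySpec(1, 500, np.array([[1.0]]), noise_sd=0.25, seed=3)
        traj, _ = gen_state_trajectory(spec)
        series = catalytic_distance_series(traj, (0, 1, 2))
        X, slices = stack_series([series])
        _, emb = deep_rf_embed(X, seed=4)
        with pytest.warns(UserWarning, match="k=1"):
            model = select_k(emb, X, slices, k_range=range(2, 5), restarts=10, seed=4)
        assert model.k == 1
        assert all(d["z"] <= 2.0 for d in model.diagnostics)

    def test_boundary_k_range_compares_against_k1(self, two_state_series):
        series, labels = two_state_series
        X, slices = stack_series([series])
        _, emb = deep_rf_embed(X, seed=6)
        model = select_k(emb, X, slices, k_range=[2], restarts=10, seed=6)
        assert model.k == 2
        assert model.diagnostics[0]["z"] > 2.0

    def test_empty_k_range_rejected(self, two_state_series):
        series, _ = two_state_series
        X, slices = stack_series([series])
        with pytest.raises(ValueError):
            select_k(np.zeros((len(X), 2)), X, slices, k_range=[])

    def test_rerun_bit_reproducible(self, two_state_series):
        series, _ = two_state_series
        X, slices = stack_series([series])
        _, emb = deep_rf_embed(X, seed=7)
        m1 = select_k(emb, X, slices, k_range=[2, 3], restarts=5, n_draws=200, seed=7)
        m2 = select_k(emb, X, slices, k_range=[2, 3], restarts=5, n_draws=200, seed=7)
        assert m1.k == m2.k
        assert np.array_equal(m1.assignment, m2.assignment)
        assert m1.diagnostics == m2.diagnostics


class TestCentralConformation:
    def test_single_member_state(self):
        vectors = np.array([[0.0, 0.0], [5.0, 5.0], [1.0, 1.0]])
        labels = np.array([0, 1, 0])
        central = central_conformation(vectors, labels)
        assert central[1] == 1

    def test_symmetric_tie_resolves_to_earliest(self):
        vectors = np.array([[0.0], [2.0]])
        labels = np.array([0, 0])
        assert central_conformation(vectors, labels)[0] == 0

    def test_zero_noise_central_frame_equals_centroid(self):
        spec = StateTrajectorySpec(2, 100, np.eye(2), noise_sd=0.0, seed=5)
        traj, labels = gen_state_trajectory(spec)
        series = catalytic_distance_series(traj, (0, 1, 2))
        central = central_conformation(series.vectors, labels)
        for s, idx in central.items():
            mean = series.vectors[labels == s].mean(axis=0)
            assert np.linalg.norm(series.vectors[idx] - mean) == pytest.approx(0.0, abs=1e-9)


class TestStateTree:
    def test_perfectly_separable_single_split(self):
        rng = np.random.default_rng(0)
        n = 400
        X = rng.normal(5.0, 0.3, size=(n, 10))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X[y == 1, 4] += 8.0  # planted discriminating distance in a gap around ~9
        tree = state_tree(X, y, [f"d{i}" for i in range(10)], xval=100, seed=0)
        assert tree.root_feature == "d4"
        assert 5.9 < tree.root_threshold < 13.0
        assert tree.accuracy(X, y) == 1.0
        assert tree.tree.get_depth() == 1

    def test_identical_class_distributions_root_only(self):
        # every distinct conformation appears in both states equally: no split
        # can reduce impurity, so nothing clears the complexity parameter
        rng = np.random.default_rng(1)
        base = rng.normal(size=(80, 5))
        X = np.vstack([base, base])
        y = np.array([0] * 80 + [1] * 80)
        tree = state_tree(X, y, [f"d{i}" for i in range(5)], xval=0, seed=1)
        assert tree.tree.get_depth() == 0
        assert tree.accuracy(X, y) == 0.5

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            state_tree(np.zeros((10, 3)), np.zeros(10, dtype=int), ["a", "b", "c"])

    def test_render_and_dict_expose_annotations(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 4))
        y = (X[:, 2] > 0).astype(int)
        tree = state_tree(X, y, ["a", "b", "c", "d"], xval=50, seed=2)
        text = tree.render()
        assert "data 1.00" in text and "c" in text
        d = tree.to_dict()
        assert d["data_fraction"] == 1.0 and "threshold" in d
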