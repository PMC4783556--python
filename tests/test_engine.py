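import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from catfuzz import (
    CategoricalDataset,
    ClusteringConfig,
    build_distance_table,
    compute_objective,
    initialize_membership,
    mode_centroid,
    point_centroid_distance,
    run_clustering,
    update_centroids,
    update_membership,
)
from catfuzz.synthetic import generate, make_separable_scenario

TOY4_U = np.array([[0.9, 0.1], [0.6, 0.4], [0.1, 0.9], [0.2, 0.8]])


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 1},
            {"m": 1.0},
            {"epsilon": 0.0},
            {"max_iter": 0},
            {"distance_kind": "euclidean"},
            {"centroid_kind": "mean"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClusteringConfig(**kwargs)


class TestInitializeMembership:
    def test_rows_sum_to_one(self):
        u = initialize_membership(5, 2, seed=0)
        assert u.shape == (5, 2)
        assert u.sum(axis=1) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        assert (initialize_membership(6, 3, 9) == initialize_membership(6, 3, 9)).all()

    def test_different_seeds_differ(self):
        assert (
            initialize_membership(6, 3, 1) != initialize_membership(6, 3, 2)
        ).any()

    def test_fewer_records_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            initialize_membership(2, 3, 0)


class TestUpdateCentroids:
    def test_hard_memberships_give_within_cluster_frequencies(self, toy4):
        u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        cents = update_centroids(toy4, u, m=1.7)
        # cluster 0 = records (x,a),(x,a); cluster 1 = (x,b),(y,b)
        assert cents[0].weights[0] == pytest.approx([1.0, 0.0])  # F1: all x
        assert cents[0].weights[1] == pytest.approx([1.0, 0.0])  # F2: all a
        assert cents[1].weights[0] == pytest.approx([0.5, 0.5])
        assert cents[1].weights[1] == pytest.approx([0.0, 1.0])

    def test_uniform_memberships_give_global_frequencies(self, toy4):
        u = np.full((4, 2), 0.5)
        cents = update_centroids(toy4, u, m=2.0)
        for c in cents:
            assert c.weights[0] == pytest.approx([0.75, 0.25])  # x,x,x,y
            assert c.weights[1] == pytest.approx([0.5, 0.5])

    def test_toy4_hand_arithmetic(self, toy4):
        # u^m = (.81,.36,.01,.04), N_c = 1.22, F1: x -> 1.18/1.22
        cents = update_centroids(toy4, TOY4_U, m=2.0)
        assert cents[0].mass == pytest.approx(1.22)
        assert cents[0].weights[0] == pytest.approx([1.18 / 1.22, 0.04 / 1.22])
        assert cents[0].weights[0][0] == pytest.approx(0.96721, abs=5e-6)

    def test_weights_sum_to_one(self, toy4):
        for c in update_centroids(toy4, TOY4_U, m=1.1):
            for w in c.weights:
                assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_cluster_rejected(self, toy4):
        u = np.array([[1, 0]] * 4, dtype=float)
        with pytest.raises(ValueError, match="zero soft mass"):
            update_centroids(toy4, u, m=2.0)


class TestPointCentroidDistance:
    def test_point_mass_on_own_values_is_zero(self, toy4):
        u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        cents = update_centroids(toy4, u, m=2.0)
        table = build_distance_table(toy4, "cooccurrence")
        assert point_centroid_distance(["x", "a"], cents[0], table) == pytest.approx(0)

    def test_hamming_gives_one_minus_own_weight(self, toy4):
        cents = update_centroids(toy4, TOY4_U, m=2.0)
        table = build_distance_table(toy4, "hamming")
        d = point_centroid_distance(["y", "b"], cents[0], table)
        expected = (1 - cents[0].weights[0][1]) + (1 - cents[0].weights[1][1])
        assert d == pytest.approx(expected)

    def test_toy4_composed_hand_arithmetic(self, toy4):
        cents = update_centroids(toy4, TOY4_U, m=2.0)
        table = build_distance_table(toy4, "cooccurrence")
        d = point_centroid_distance(["y", "b"], cents[0], table)
        omega_f1 = (1.18 / 1.22) * (2 / 3)  # ~0.64481
        omega_f2 = (1.17 / 1.22) * 0.5  # F2 weight of a times delta(b, a)
        assert omega_f1 == pytest.approx(0.64481, abs=5e-6)
        assert d == pytest.approx(omega_f1 + omega_f2)

    def test_unknown_value_raises(self, toy4):
        cents = update_centroids(toy4, TOY4_U, m=2.0)
        table = build_distance_table(toy4, "cooccurrence")
        with pytest.raises(KeyError):
            point_centroid_distance(["z", "a"], cents[0], table)


class TestUpdateMembership:
    def test_equal_distances_split_evenly(self):
        u = update_membership(np.array([[0.4, 0.4]]), m=1.3)
        assert u[0] == pytest.approx([0.5, 0.5])

    def test_zero_distance_takes_all(self):
        u = update_membership(np.array([[0.0, 0.7]]), m=2.0)
        assert u[0] == pytest.approx([1.0, 0.0])

    def test_two_zero_distances_split(self):
        u = update_membership(np.array([[0.0, 0.0, 0.3]]), m=2.0)
        assert u[0] == pytest.approx([0.5, 0.5, 0.0])

    def test_m2_inverse_distance_weights(self):
        u = update_membership(np.array([[0.2, 0.8]]), m=2.0)
        assert u[0] == pytest.approx([0.8, 0.2])

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            update_membership(np.array([[-0.1, 0.5]]), m=2.0)

    def test_rows_always_sum_to_one(self):
        rng = np.random.default_rng(5)
        d = rng.random((50, 4)) * 3
        d[rng.random(50) < 0.2, 0] = 0.0
        for m in (1.1, 1.5, 1.9):
            u = update_membership(d, m)
            assert u.sum(axis=1) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numerical_minimizer_of_objective(self):
        # On a tiny instance with fixed distances, the closed-form update
        # must attain the minimum of J over the probability simplex. With
        # K = 2 each row is (t, 1 - t), so rows can be minimised exactly
        # by an independent scalar search.
        d = np.array([[0.3, 0.9], [0.5, 0.2], [0.7, 0.6]])
        m = 1.5
        u_closed = update_membership(d, m)
        for i in range(3):
            row = minimize_scalar(
                lambda t: t**m * d[i, 0] + (1 - t) ** m * d[i, 1],
                bounds=(0.0, 1.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            assert u_closed[i, 0] == pytest.approx(row.x, abs=1e-6)


class TestObjective:
    def test_zero_distances_give_zero(self):
        assert compute_objective(np.array([[1.0, 0.0]]), np.zeros((1, 2)), 1.5) == 0

    def test_indicator_membership_picks_own_distance(self):
        j = compute_objective(np.array([[1.0, 0.0]]), np.array([[0.3, 9.0]]), 1.9)
        assert j == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        j = compute_objective(
            np.array([[0.8, 0.2]]), np.array([[0.2, 0.8]]), m=2.0
        )
        assert j == pytest.approx(0.16)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_objective(np.ones((2, 2)), np.ones((3, 2)), 2.0)


class TestModeCentroid:
    def test_hard_memberships_reduce_to_counting(self, toy4):
        u = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        centres = mode_centroid(toy4, u, m=1.2)
        assert centres[0] == ("x", "a")
        # cluster 1 = (x,b),(y,b): F1 tie between x and y -> "x" wins
        assert centres[1] == ("x", "b")

    def test_toy4_weighted_mode(self, toy4):
        centres = mode_centroid(toy4, TOY4_U, m=2.0)
        assert centres[0][0] == "x"  # weight 1.18 > 0.04

    def test_exact_tie_goes_to_first_vocabulary_value(self):
        ds = CategoricalDataset.from_cells(
            [["b", "k"], ["a", "k"], ["a", "k"], ["b", "k"]]
        )
        u = np.full((4, 2), 0.5)
        centres = mode_centroid(ds, u, m=2.0)
        assert centres[0][0] == "a"


def two_block_dataset():
    """Two homogeneous blocks differing in every feature."""
    block_a = [["a", "p", "u"]] * 5
    block_b = [["b", "q", "v"]] * 4
    labels = ["A"] * 5 + ["B"] * 4
    return CategoricalDataset.from_cells(block_a + block_b, labels=labels)


class TestRunClustering:
    @pytest.mark.parametrize("distance_kind", ["cooccurrence", "hamming"])
    @pytest.mark.parametrize("centroid_kind", ["fuzzy", "mode"])
    def test_separates_homogeneous_blocks(self, distance_kind, centroid_kind):
        ds = two_block_dataset()
        config = ClusteringConfig(
            distance_kind=distance_kind, centroid_kind=centroid_kind, seed=5
        )
        result = run_clustering(ds, config)
        hard = result.hard_labels()
        # perfect split up to label swap
        assert len(set(hard[:5])) == 1
        assert len(set(hard[5:])) == 1
        assert hard[0] != hard[-1]

    def test_huge_epsilon_stops_after_one_iteration(self, toy4):
        result = run_clustering(toy4, ClusteringConfig(epsilon=1e9, seed=1))
        assert result.iterations == 1
        assert result.converged
        assert len(result.objective_trace) == 1

    def test_same_seed_reproduces_trace_bitwise(self):
        ds = generate(make_separable_scenario(100, 4, 2, 0.2, seed=0))
        cfg = ClusteringConfig(seed=11)
        t1 = run_clustering(ds, cfg).objective_trace
        t2 = run_clustering(ds, cfg).objective_trace
        assert t1 == t2

    def test_mismatched_table_kind_rejected(self, toy4):
        table = build_distance_table(toy4, "hamming")
        with pytest.raises(ValueError, match="does not match"):
            run_clustering(toy4, ClusteringConfig(distance_kind="cooccurrence"), table)

    def test_column_permutation_equivariance(self):
        ds = generate(make_separable_scenario(80, 4, 2, 0.2, seed=2))
        u0 = initialize_membership(ds.n, 2, seed=3)
        cfg = ClusteringConfig(seed=3)
        res = run_clustering(ds, cfg, initial_membership=u0)
        res_swapped = run_clustering(ds, cfg, initial_membership=u0[:, ::-1])
        assert res_swapped.memberships == pytest.approx(
            res.memberships[:, ::-1], abs=1e-12
        )
        assert res_swapped.objective_trace == pytest.approx(res.objective_trace)

    def test_row_and_centroid_normalization_each_iteration(self):
        ds = generate(make_separable_scenario(60, 4, 2, 0.3, seed=4))
        table = build_distance_table(ds, "cooccurrence")
        cells = ds.cells()
        u = initialize_membership(ds.n, 2, seed=7)
        for _ in range(5):
            cents = update_centroids(ds, u, m=1.1)
            for c in cents:
                for w in c.weights:
                    assert w.sum() == pytest.approx(1.0, abs=1e-9)
            d = np.array(
                [
                    [point_centroid_distance(row, c, table) for c in cents]
                    for row in cells
                ]
            )
            assert (d >= 0).all()
            u = update_membership(d, m=1.1)
            assert u.sum(axis=1) == pytest.approx(1.0, abs=1e-9)

    def test_near_hard_memberships_as_m_approaches_one(self):
        ds = generate(make_separable_scenario(200, 6, 2, 0.05, seed=6))
        result = run_clustering(ds, ClusteringConfig(m=1.01, seed=8))
        assert result.memberships.max(axis=1).min() >= 0.99

    def test_hamming_fuzzy_centroid_distance_identity(self):
        # With the Hamming table, Omega_l = 1 - centroid weight of the
        # record's own value; the engine's distances must obey it.
        ds = generate(make_separable_scenario(60, 3, 2, 0.3, seed=9))
        table = build_distance_table(ds, "hamming")
        cfg = ClusteringConfig(distance_kind="hamming", max_iter=3, seed=10)
        result = run_clustering(ds, cfg, table=table)
        cents = update_centroids(ds, result.memberships, m=cfg.m)
        for i in (0, 7, 33):
            for j, c in enumerate(cents):
                expected = sum(
                    1.0 - c.weights[l][ds.codes[i, l]] for l in range(ds.s)
                )
                d = point_centroid_distance(ds.cells()[i], c, table)
                assert d == pytest.approx(expected, abs=1e-12)
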