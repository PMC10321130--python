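import numpy as np
import pytest

from eegclust.clustering import (
    ClusterConfig,
    CuckooParams,
    DragonflyParams,
    FCMConfig,
    FireflyParams,
    cluster,
    clustering_objective,
    cuckoo_cluster,
    dragonfly_cluster,
    dragonfly_forces,
    fcm_cluster,
    fcm_select_k,
    firefly_cluster,
    firefly_kernel,
    firefly_move,
    kmeans_cluster,
    levy_flight_step,
    modified_firefly_cluster,
    _fcm_memberships,
)
from conftest import exhaustive_sse_optimum, two_blob

METAHEURISTICS = {
    "cuckoo": cuckoo_cluster,
    "dragonfly": dragonfly_cluster,
    "firefly": firefly_cluster,
    "modified_firefly": modified_firefly_cluster,
}


class TestObjective:
    def test_zero_when_points_sit_on_centroids(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        obj, labels = clustering_objective(X, X, q=2)
        assert obj == 0.0
        assert list(labels) == [0, 1]

    def test_simple_arithmetic(self):
        obj, _ = clustering_objective(np.array([[0.0], [2.0]]), np.array([[1.0]]), q=2)
        assert obj == pytest.approx(2.0)

    def test_kmeans_assignment_attains_exhaustive_optimum(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (8, 2))
        optimum = exhaustive_sse_optimum(X)
        model = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=20))
        assert model.objective == pytest.approx(optimum, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            clustering_objective(np.empty((0, 2)), np.zeros((1, 2)))


class TestKMeans:
    def test_two_blob_centroids_are_blob_means(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        model = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=5))
        assert model.objective == pytest.approx(exhaustive_sse_optimum(X), rel=1e-12)
        got = sorted(map(tuple, np.round(model.centroids, 9)))
        assert got == [(0.0, 0.5), (10.0, 0.5)]

    def test_k1_mean_and_median(self):
        X = np.array([[0.0], [0.0], [10.0]])
        mean_model = kmeans_cluster(X, ClusterConfig(k=1, q=2, seed=0))
        assert mean_model.centroids[0, 0] == pytest.approx(10.0 / 3.0)
        med_model = kmeans_cluster(X, ClusterConfig(k=1, q=1, seed=0))
        assert med_model.centroids[0, 0] == 0.0

    def test_global_optimum_small_instances(self):
        """Best of 20 restarts matches assignment enumeration on n <= 10."""
        for seed, n in [(0, 6), (1, 8), (2, 10)]:
            X = np.random.default_rng(seed).normal(0, 1, (n, 2))
            model = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=20))
            assert model.objective == pytest.approx(
                exhaustive_sse_optimum(X), rel=1e-9
            )

    def test_objective_trace_non_increasing(self):
        X = two_blob(4)
        model = kmeans_cluster(X, ClusterConfig(k=2, seed=1))
        assert all(b <= a + 1e-9 for a, b in zip(model.trace, model.trace[1:]))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 1)), ClusterConfig(k=4))

    def test_bit_reproducible(self):
        X = two_blob(9)
        a = kmeans_cluster(X, ClusterConfig(k=2, seed=3))
        b = kmeans_cluster(X, ClusterConfig(k=2, seed=3))
        assert np.array_equal(a.centroids, b.centroids)


class TestFCM:
    def test_membership_one_at_centroid(self):
        centroids = np.array([[0.0], [5.0]])
        Z = _fcm_memberships(np.array([[0.0]]), centroids, p=2.0)
        assert np.allclose(Z, [[1.0, 0.0]])

    def test_equidistant_point_gets_half_half(self):
        centroids = np.array([[0.0], [2.0]])
        Z = _fcm_memberships(np.array([[1.0]]), centroids, p=2.0)
        assert np.allclose(Z, [[0.5, 0.5]])

    def test_fixed_point_oracle_two_points(self):
        """Direct update-iteration converges to the same fixed point."""
        X = np.array([[0.0], [1.0]])
        model = fcm_cluster(X, FCMConfig(k=2, p=2.0, seed=0))
        # independent fixed-point iteration of the coupled updates
        Z = np.array([[0.9, 0.1], [0.2, 0.8]])
        for _ in range(10_000):
            Zp = Z**2
            W = (Zp.T @ X) / Zp.sum(axis=0)[:, None]
            D = np.abs(X - W.T)
            Z = np.zeros_like(D)
            for i in range(2):
                if np.any(D[i] == 0.0):  # zero-distance limit: one-hot
                    Z[i, np.argmin(D[i])] = 1.0
                else:
                    inv = D[i] ** -2.0
                    Z[i] = inv / inv.sum()
        assert np.allclose(
            np.sort(model.centroids[:, 0]), np.sort(W[:, 0]), atol=1e-6
        )

    def test_rows_sum_to_one(self):
        X = two_blob(1)
        model = fcm_cluster(X, FCMConfig(k=3, seed=2))
        assert np.allclose(model.memberships.sum(axis=1), 1.0, atol=1e-12)

    def test_trace_non_increasing(self):
        X = two_blob(5)
        model = fcm_cluster(X, FCMConfig(k=2, seed=4))
        assert all(b <= a + 1e-7 for a, b in zip(model.trace, model.trace[1:]))

    def test_near_hard_limit_matches_kmeans(self):
        """p -> 1+ drives memberships to the k-means hard assignment."""
        X = two_blob(2)
        hard = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=10))
        soft = fcm_cluster(X, FCMConfig(k=2, p=1.05, seed=0))
        assert np.max(np.abs(np.sort(soft.memberships.max(axis=1)) - 1.0)) < 1e-3
        assert soft.objective == pytest.approx(hard.objective, rel=0.01)


class TestFCMSelectK:
    def test_single_candidate(self):
        X = two_blob(0)
        assert fcm_select_k(X, k_min=3, k_max=3) == 3

    def test_recovers_three_blobs(self):
        rng = np.random.default_rng(8)
        X = np.vstack(
            [rng.normal(c, 0.5, (20, 2)) for c in ((0, 0), (10, 0), (5, 9))]
        )
        assert fcm_select_k(X, k_min=2, k_max=7, seed=0) == 3

    def test_duplicated_blobs_prefer_two(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(0, 0.4, (15, 2))
        blob_b = rng.normal(8, 0.4, (15, 2))
        X = np.vstack([blob_a, blob_a + 0.01, blob_b, blob_b + 0.01])
        assert fcm_select_k(X, k_min=2, k_max=4, seed=1) == 2

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            fcm_select_k(two_blob(0), k_min=5, k_max=3)


class TestLevyFlight:
    def test_deterministic(self):
        a = levy_flight_step(6, 1.5, 1.0, seed=9)
        b = levy_flight_step(6, 1.5, 1.0, seed=9)
        assert np.array_equal(a, b)

    def test_zero_scale_gives_zero_vector(self):
        assert np.array_equal(levy_flight_step(4, 1.5, 0.0, seed=0), np.zeros(4))

    def test_tail_exponent(self):
        """Empirical survival-function slope near -beta for beta = 1.5."""
        steps = np.abs(levy_flight_step(100_000, 1.5, 1.0, seed=1))
        ts = np.quantile(steps, [0.95, 0.99, 0.999])
        surv = np.array([np.mean(steps > t) for t in ts])
        slope = np.polyfit(np.log(ts), np.log(surv), 1)[0]
        assert abs(slope - (-1.5)) <= 0.3

    def test_beta_range_validated(self):
        with pytest.raises(ValueError):
            levy_flight_step(3, 2.5, 1.0)


class TestCuckoo:
    def test_elitist_trace_monotone(self):
        X = two_blob(0)
        model = cuckoo_cluster(X, ClusterConfig(k=2), CuckooParams(seed=0, iters=50))
        assert all(b <= a for a, b in zip(model.trace, model.trace[1:]))

    def test_pa_zero_means_no_abandonment(self):
        X = two_blob(1)
        model = cuckoo_cluster(
            X, ClusterConfig(k=2), CuckooParams(seed=0, pa=0.0, iters=30)
        )
        assert model.meta["n_abandoned"] == 0

    def test_two_blob_matches_kmeans_within_one_percent(self):
        X = two_blob(3, n_per_blob=20)
        km = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=20)).objective
        model = cuckoo_cluster(X, ClusterConfig(k=2), CuckooParams(seed=3))
        assert model.objective <= km * 1.01


class TestDragonflyForces:
    def test_coincident_swarm_has_zero_sep_and_co(self):
        pos = np.ones((4, 3))
        vel = np.zeros_like(pos)
        sep, ali, co, food, ene = dragonfly_forces(
            0, pos, vel, np.zeros(3), np.zeros(3), radius=1.0
        )
        assert np.array_equal(sep, np.zeros(3))
        assert np.array_equal(co, np.zeros(3))

    def test_no_neighbors_convention(self):
        pos = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        vel = np.ones_like(pos)
        sep, ali, co, food, ene = dragonfly_forces(
            0, pos, vel, np.array([1.0, 0.0]), np.array([0.0, 1.0]), radius=1.0
        )
        for v in (sep, ali, co):
            assert np.array_equal(v, np.zeros(2))
        assert np.array_equal(food, [1.0, 0.0])
        assert np.array_equal(ene, [0.0, -1.0])

    def test_hand_computed_three_agent_forces(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        vel = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, 3.0]])
        sep, ali, co, food, ene = dragonfly_forces(
            0, pos, vel, np.array([5.0, 5.0]), np.array([-5.0, 0.0]), radius=3.0
        )
        # neighbors: agents 1 and 2
        assert np.allclose(sep, (0 - 1 + 0 - 0, 0 - 0 + 0 - 2))
        assert np.allclose(ali, ((1 - 1) / 2, (1 + 3) / 2))
        assert np.allclose(co, (0.5 - 0.0, 1.0 - 0.0))
        assert np.allclose(food, (5.0, 5.0))
        assert np.allclose(ene, (5.0, 0.0))


class TestDragonfly:
    def test_zero_weights_zero_inertia_is_static(self):
        X = two_blob(0, n_per_blob=5)
        params = DragonflyParams(
            w_sep=0, w_ali=0, w_coh=0, w_food=0, w_enemy=0, inertia=0,
            seed=0, iters=10,
        )
        model = dragonfly_cluster(X, ClusterConfig(k=2), params)
        assert len(set(np.round(model.trace, 12))) == 1

    def test_trace_monotone(self):
        X = two_blob(2)
        model = dragonfly_cluster(
            X, ClusterConfig(k=2), DragonflyParams(seed=1, iters=60)
        )
        assert all(b <= a for a, b in zip(model.trace, model.trace[1:]))

    def test_two_blob_within_five_percent_of_kmeans(self):
        X = two_blob(4)
        km = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=20)).objective
        model = dragonfly_cluster(X, ClusterConfig(k=2), DragonflyParams(seed=4))
        assert model.objective <= km * 1.05


class TestFireflyKernel:
    @pytest.mark.parametrize(
        "q,v0,lam,expected",
        [(0.0, 3.0, 2.0, 3.0), (1.0, 1.0, 1.0, 0.5), (5.0, 7.0, 0.0, 7.0)],
    )
    def test_values(self, q, v0, lam, expected):
        assert firefly_kernel(q, v0, lam) == pytest.approx(expected)

    def test_strictly_decreasing_for_positive_lam(self):
        vals = [firefly_kernel(q, 1.0, 0.7) for q in (0.0, 0.5, 1.0, 2.0)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            firefly_kernel(-1.0, 1.0, 1.0)


class TestFireflyMove:
    def test_stationary_at_brightest_with_zero_alpha(self):
        y = np.array([1.0, 2.0])
        p = FireflyParams(alpha=0.0)
        assert np.allclose(firefly_move(y, y, p, np.zeros(2)), y)

    def test_full_attraction_with_zero_absorption(self):
        p = FireflyParams(alpha=0.0, lam=0.0, a0=1.0)
        y, yb = np.array([0.0, 0.0]), np.array([3.0, -4.0])
        assert np.allclose(firefly_move(y, yb, p, np.zeros(2)), yb)

    def test_intensity_ratio_attraction_is_scalable(self):
        p = FireflyParams(alpha=0.0, lam=0.0)
        y, yb = np.zeros(2), np.array([2.0, 0.0])
        # B0 = J0'/J0 = 2 doubles the attraction step
        moved = firefly_move(y, yb, p, np.zeros(2), attraction=2.0)
        assert np.allclose(moved, [4.0, 0.0])


class TestFireflyClusterers:
    def test_population_of_one_is_a_random_walk_archive(self):
        X = two_blob(0, n_per_blob=5)
        model = firefly_cluster(
            X, ClusterConfig(k=2), FireflyParams(n_fireflies=1, seed=0, iters=40)
        )
        assert all(b <= a for a, b in zip(model.trace, model.trace[1:]))
        assert model.objective == pytest.approx(min(model.trace), rel=1e-12)

    @pytest.mark.parametrize("fn", [firefly_cluster, modified_firefly_cluster])
    def test_two_blob_within_five_percent_of_kmeans(self, fn):
        X = two_blob(6)
        km = kmeans_cluster(X, ClusterConfig(k=2, seed=0, n_init=20)).objective
        model = fn(X, ClusterConfig(k=2), FireflyParams(seed=6))
        assert model.objective <= km * 1.05

    def test_modified_population_best_never_worsens(self):
        X = two_blob(1)
        model = modified_firefly_cluster(
            X, ClusterConfig(k=2), FireflyParams(seed=2, iters=50)
        )
        pop = model.meta["population_best_trace"]
        assert all(b <= a for a, b in zip(pop, pop[1:]))

    def test_guided_elite_improves_at_least_as_fast_as_random_walk(self):
        """With many probe directions the elite's average per-iteration gain
        matches or beats the standard random-walk elite (paired seeds)."""
        gains_std, gains_mod = [], []
        for seed in range(20):
            X = two_blob(seed, n_per_blob=8)
            cfg = ClusterConfig(k=1)
            p_std = FireflyParams(seed=seed, iters=30)
            p_mod = FireflyParams(seed=seed, iters=30, s_directions=64)
            m_std = firefly_cluster(X, cfg, p_std)
            m_mod = modified_firefly_cluster(X, cfg, p_mod)
            gains_std.append((m_std.trace[0] - m_std.trace[-1]) / 30)
            gains_mod.append((m_mod.trace[0] - m_mod.trace[-1]) / 30)
        assert np.mean(gains_mod) >= np.mean(gains_std)


class TestCrossAlgorithmInvariants:
    @pytest.mark.parametrize(
        "method", ["kmeans", "kmedian", "fcm", "cuckoo", "dragonfly", "firefly",
                   "modified_firefly"]
    )
    def test_stored_objective_matches_recomputation(self, method):
        from eegclust.clustering import fcm_objective

        X = two_blob(7, n_per_blob=10)
        model = cluster(X, method, k=2, seed=5)
        if method == "fcm":
            recomputed = fcm_objective(X, model.centroids, model.memberships, 2.0)
        else:
            q = 1 if method == "kmedian" else 2
            recomputed, _ = clustering_objective(X, model.centroids, q=q)
        assert model.objective == pytest.approx(recomputed, abs=1e-9)

    @pytest.mark.parametrize(
        "method", ["cuckoo", "dragonfly", "firefly", "modified_firefly"]
    )
    def test_bit_reproducible(self, method):
        X = two_blob(8, n_per_blob=8)
        a = cluster(X, method, k=2, seed=13)
        b = cluster(X, method, k=2, seed=13)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.trace == b.trace
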