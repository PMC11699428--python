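"""Firefly clustering: objective, search, K-means refinement, labelling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from abmff.firefly import (ClusterSolution, FireflyConfig, assign_labels,
                           clustering_objective, firefly_search,
                           intensity_histogram, kmeans_refine,
                           optimize_centroids)


def hist_of(values):
    return np.bincount(np.asarray(values, dtype=np.int64), minlength=256)


class TestObjective:
    def test_hand_example_with_separation_reward(self):
        # two perfect clusters: intra 0, separation 100, alpha 0.6
        assert clustering_objective(hist_of([0, 0, 10, 10]), [0, 10], 0.6) == -60.0

    def test_single_cluster_has_no_separation_term(self):
        j = clustering_objective(hist_of([2, 4, 6]), [4.0], 0.6)
        assert j == pytest.approx((2 - 4) ** 2 + 0 + (6 - 4) ** 2)

    def test_quarter_distances(self):
        j = clustering_objective(hist_of([1, 2, 9, 10]), [1.5, 9.5], 0.0)
        assert j == pytest.approx(1.0)

    @given(seed=st.integers(0, 2 ** 20), k=st.integers(1, 4))
    def test_histogram_equals_per_pixel_evaluation(self, seed, k,
                                                   naive_objective_oracle):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (5, 5))
        mu = rng.uniform(0, 255, k)
        fast = clustering_objective(intensity_histogram(img), mu, 0.6)
        assert fast == pytest.approx(naive_objective_oracle(img, mu, 0.6),
                                     rel=1e-12, abs=1e-9)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            clustering_objective(np.zeros(256), [10.0])


class TestFireflySearch:
    def test_recovers_two_delta_masses(self):
        h = np.zeros(256, int)
        h[50] = 128
        h[200] = 128
        sol = firefly_search(h, 2, FireflyConfig(seed=3))
        assert np.all(np.abs(sol.centroids - np.array([50.0, 200.0])) < 1.0)

    def test_fixed_seed_is_deterministic(self):
        h = hist_of(np.random.default_rng(0).integers(0, 256, 400))
        a = firefly_search(h, 3, FireflyConfig(seed=9))
        b = firefly_search(h, 3, FireflyConfig(seed=9))
        assert np.array_equal(a.centroids, b.centroids)
        assert a.objective == b.objective

    def test_best_objective_trace_never_increases(self):
        h = hist_of(np.random.default_rng(1).integers(0, 256, 300))
        _, trace = firefly_search(h, 2, FireflyConfig(seed=4, iter2=40),
                                  return_history=True)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_single_centroid_lands_on_the_mean(self):
        vals = [10, 20, 30, 40]
        sol = optimize_centroids(hist_of(vals), 1, FireflyConfig(seed=5))
        assert abs(sol.centroids[0] - np.mean(vals)) < 1.0

    def test_k_beyond_distinct_intensities_rejected(self):
        with pytest.raises(ValueError):
            firefly_search(hist_of([7, 7, 7]), 2, FireflyConfig(seed=0))


class TestKMeansRefine:
    def test_hand_example_converges_to_half_means(self):
        sol = kmeans_refine(hist_of([0, 1, 9, 10]), [0.0, 10.0])
        assert np.allclose(sol.centroids, [0.5, 9.5])

    def test_exact_means_are_a_fixed_point(self):
        h = hist_of([10, 10, 30, 30])
        sol, jk = kmeans_refine(h, [10.0, 30.0], return_history=True)
        assert np.allclose(sol.centroids, [10.0, 30.0])
        assert len(jk) == 1  # converged immediately

    @given(seed=st.integers(0, 2 ** 20))
    def test_within_cluster_cost_descends(self, seed):
        rng = np.random.default_rng(seed)
        h = hist_of(rng.integers(0, 256, 200))
        init = rng.uniform(0, 255, 3)
        _, jk = kmeans_refine(h, init, return_history=True)
        assert all(b <= a + 1e-9 for a, b in zip(jk, jk[1:]))

    def test_empty_cluster_is_reseeded(self):
        # second centroid attracts nothing; it must be re-seeded on data
        sol = kmeans_refine(hist_of([10, 10, 20, 20]), [15.0, 200.0])
        assert sol.k == 2
        assert np.all(sol.centroids <= 20.0)


class TestAssignLabels:
    def test_nearest_centroid_and_midpoint_tie_break(self):
        sol = ClusterSolution(np.array([50.0, 200.0]), 0.0)
        img = np.array([[40, 210, 125]], dtype=np.uint8)
        assert assign_labels(img, sol).tolist() == [[1, 2, 1]]

    def test_constant_image_single_label(self):
        sol = ClusterSolution(np.array([10.0, 90.0, 250.0]), 0.0)
        labels = assign_labels(np.full((4, 4), 251, np.uint8), sol)
        assert set(np.unique(labels)) == {3}

    def test_centroid_permutation_permutes_labels_only(self):
        img = np.random.default_rng(2).integers(0, 256, (8, 8)).astype(np.uint8)
        mu = np.array([30.0, 130.0, 230.0])
        h = intensity_histogram(img)
        a = assign_labels(img, ClusterSolution(mu, 0.0))
        b = assign_labels(img, ClusterSolution(mu[::-1].copy(), 0.0))
        assert np.array_equal(a, 4 - b)  # reversed order -> reversed labels
        assert clustering_objective(h, mu) == pytest.approx(
            clustering_objective(h, mu[::-1].copy()))


def test_solution_invariants():
    with pytest.raises(ValueError):
        ClusterSolution(np.array([-1.0, 10.0]), 0.0)
    sol = ClusterSolution(np.array([5.0]), 12.5)
    assert sol.brightness == -12.5
    with pytest.raises(ValueError):
        FireflyConfig(swarm_size=1)
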