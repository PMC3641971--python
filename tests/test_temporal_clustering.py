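"""k-means recovery, k estimation, profiles, and dendrogram ordering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from promoshift.synthetic_data import default_templates, simulate_expression
from promoshift.temporal_clustering import (
    ClusterProfile,
    cluster_profiles,
    estimate_k,
    hierarchical_order,
    kmeans_cluster,
    normalize_for_display,
)


@pytest.fixture
def planted_profiles(rng):
    templates = default_templates(3, 2.0)
    assign = {f"t{i:03d}": i % 3 for i in range(150)}
    expr = simulate_expression(templates, assign, 0.0, 4, rng)
    return expr, assign


class TestKmeans:
    def test_k1_centroid_is_column_mean(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(20, 5)))
        res = kmeans_cluster(profiles, k=1, seed=0)
        assert (res.labels == 1).all()
        # inertia of the single cluster equals SS around the column mean
        want = ((profiles - profiles.mean()) ** 2).to_numpy().sum()
        assert res.inertia == pytest.approx(want)

    def test_recovers_planted_partition_exactly(self, planted_profiles):
        expr, assign = planted_profiles
        res = kmeans_cluster(expr.replicate_means(), k=3, seed=0)
        truth = [assign[t] for t in res.labels.index]
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_deterministic_given_seed(self, planted_profiles):
        expr, _ = planted_profiles
        a = kmeans_cluster(expr.replicate_means(), k=3, seed=7)
        b = kmeans_cluster(expr.replicate_means(), k=3, seed=7)
        assert (a.labels == b.labels).all()

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(pd.DataFrame(rng.normal(size=(5, 3))), k=6)

    def test_labels_dense_and_sizes_sum(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(100, 5)))
        res = kmeans_cluster(profiles, k=8, seed=1)
        assert set(res.labels) == set(range(1, 9))
        assert res.sizes.sum() == 100


class TestEstimateK:
    def test_recommends_true_k_on_separated_templates(self, rng):
        templates = default_templates(30, 2.0)[[0, 12, 20, 24, 27]]
        assign = {f"t{i}": i % 5 for i in range(300)}
        expr = simulate_expression(templates, assign, 0.2, 4, rng)
        _, rec = estimate_k(expr.replicate_means(), range(2, 11), seed=0)
        assert rec == 5

    def test_identical_profiles_flagged_no_recommendation(self):
        profiles = pd.DataFrame(np.ones((40, 5)))
        table, rec = estimate_k(profiles, range(2, 5))
        assert rec is None
        assert table["silhouette"].isna().all()

    def test_single_k_range(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(80, 5)))
        table, rec = estimate_k(profiles, range(30, 31), seed=0)
        assert len(table) == 1 and rec == 30


class TestProfiles:
    def test_singleton_cluster_profile_equals_member(self, rng):
        templates = default_templates(2, 2.0)
        expr = simulate_expression(templates, {"a": 0, "b": 1}, 0.0, 4, rng)
        res = kmeans_cluster(expr.replicate_means(), k=2, seed=0)
        for p in cluster_profiles(res, expr):
            member = res.members(p.label)[0]
            assert np.allclose(p.mean_profile, expr.replicate_means().loc[member])
            assert p.n == 1

    def test_member_counts_sum_to_de_set(self, planted_profiles):
        expr, _ = planted_profiles
        res = kmeans_cluster(expr.replicate_means(), k=3, seed=0)
        profs = cluster_profiles(res, expr)
        assert sum(p.n for p in profs) == expr.n_transcripts

    def test_cluster_mean_tracks_template_within_standard_error(self, rng):
        templates = default_templates(1, 2.0)
        assign = {f"t{i}": 0 for i in range(200)}
        expr = simulate_expression(templates, assign, 0.3, 4, rng)
        res = kmeans_cluster(expr.replicate_means(), k=1, seed=0)
        prof = cluster_profiles(res, expr)[0]
        se = 0.3 / np.sqrt(4 * 200)
        assert (np.abs(prof.mean_profile.to_numpy() - templates[0]) < 3 * se * 2).all()

    def test_display_normalization_bounds_and_flat_row(self):
        profiles = pd.DataFrame([[0.7] * 5, [2.0, -1.0, 0.0, 1.0, -2.0]])
        normed = normalize_for_display(profiles)
        assert np.allclose(normed.iloc[0], 1.0)
        assert normed.to_numpy().max() <= 1.0 and normed.to_numpy().min() >= -1.0


class TestHierarchicalOrder:
    @staticmethod
    def _profiles(vectors):
        return [
            ClusterProfile(i + 1, pd.Series(v), 10) for i, v in enumerate(vectors)
        ]

    def test_two_clusters_identity_or_swap(self):
        order = hierarchical_order(self._profiles([(0, 0), (1, 1)]))
        assert sorted(order) == [1, 2]

    def test_near_identical_clusters_adjacent(self):
        order = hierarchical_order(
            self._profiles([(1, 1), (-1, -1), (1.1, 1.1)])
        )
        i, j = order.index(1), order.index(3)
        assert abs(i - j) == 1

    def test_adjacency_invariant_under_input_permutation(self):
        vectors = [(1, 1), (-1, -1), (1.1, 1.1), (5, 5)]
        base = hierarchical_order(self._profiles(vectors))
        perm = [2, 0, 3, 1]
        relabel = {new + 1: perm[new] + 1 for new in range(4)}
        permuted = hierarchical_order(self._profiles([vectors[i] for i in perm]))
        mapped = [relabel[l] for l in permuted]

        def adjacency(order):
            return {frozenset(p) for p in zip(order, order[1:])}

        # the near pair (1,3) stays adjacent however the input is ordered
        assert frozenset((1, 3)) in adjacency(base)
        assert frozenset((1, 3)) in adjacency(mapped)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(self._profiles([(0, 0)]))
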