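"""Correlation-distance clustering against brute-force and scipy oracles."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from sageprev.clustering import (
    ClusteringConfig,
    choose_k,
    correlation_distance,
    hierarchical,
    kmeans,
    kmeans_objective,
    pairwise_correlation_distance,
)


def two_blobs(rng, n_per=3, p=12, sep=5.0):
    """Two well-separated groups of correlated profiles."""
    base_a = rng.random(p)
    base_b = -base_a + sep
    rows = [base_a + rng.normal(0, 0.01, p) for _ in range(n_per)]
    rows += [base_b + rng.normal(0, 0.01, p) for _ in range(n_per)]
    return np.array(rows)


class TestCorrelationDistance:
    def test_self_distance_zero(self, rng):
        x = rng.random(50)
        assert correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self, rng):
        x = rng.random(50)
        assert correlation_distance(x, -x + 3.0) == pytest.approx(2.0, abs=1e-12)

    def test_matches_covariance_formula(self, rng):
        for _ in range(20):
            x, y = rng.random(50), rng.random(50)
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert correlation_distance(x, y) == pytest.approx(1.0 - r, abs=1e-12)

    def test_zero_variance_convention(self, rng):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = correlation_distance(np.ones(10), rng.random(10))
        assert d == 1.0

    def test_pairwise_matches_scalar(self, rng):
        rows = rng.random((6, 20))
        d = pairwise_correlation_distance(rows)
        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(correlation_distance(rows[i], rows[j]), abs=1e-10)


def exhaustive_two_partition(rows):
    """Best 2-partition by total correlation distance to cluster means."""
    n = len(rows)
    best, best_obj = None, np.inf
    for mask in range(1, 2 ** (n - 1)):  # row 0 always in group 0
        groups = [[], []]
        for i in range(n):
            groups[(mask >> i) & 1].append(i)
        if not groups[0] or not groups[1]:
            continue
        labels = {i: g for g in (0, 1) for i in groups[g]}
        obj = kmeans_objective(rows, labels)
        if obj < best_obj:
            best_obj, best = obj, groups
    return frozenset(frozenset(g) for g in best)


class TestKMeans:
    def test_k_equals_n_every_row_own_cluster(self, rng):
        rows = rng.random((5, 8))
        assignment = kmeans(rows, ClusteringConfig(k=5))
        assert sorted(assignment.sizes.values()) == [1] * 5

    def test_k_one_single_cluster(self, rng):
        rows = rng.random((7, 8))
        assignment = kmeans(rows, ClusteringConfig(k=1))
        assert assignment.sizes == {0: 7}

    def test_k_greater_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.random((3, 5)), ClusteringConfig(k=4))

    def test_two_blobs_match_exhaustive_oracle(self, rng):
        rows = two_blobs(rng, n_per=3)
        assignment = kmeans(rows, ClusteringConfig(k=2))
        found = frozenset(
            frozenset(assignment.members(c)) for c in set(assignment.labels.values())
        )
        assert found == exhaustive_two_partition(rows)
        assert found == frozenset({frozenset({0, 1, 2}), frozenset({3, 4, 5})})

    def test_objective_non_increasing(self, rng):
        # run to convergence, then verify iterating further never worsens it
        rows = rng.random((20, 10))
        prev = None
        for max_iter in range(1, 8):
            assignment = kmeans(rows, ClusteringConfig(k=4, max_iter=max_iter))
            obj = kmeans_objective(rows, assignment.labels)
            if prev is not None:
                assert obj <= prev + 1e-9
            prev = obj

    def test_deterministic_across_runs(self, rng):
        rows = rng.random((15, 10))
        a = kmeans(rows, ClusteringConfig(k=4))
        b = kmeans(rows, ClusteringConfig(k=4, seed=99))  # seed is inert
        assert a.labels == b.labels


class TestChooseK:
    def test_outlier_isolated_as_singleton(self, rng):
        rows = np.vstack([two_blobs(rng, n_per=4), rng.normal(50, 30, (1, 12))])
        k, assignment = choose_k(rows, ClusteringConfig(k=1), k_max=9)
        assert assignment.singleton_clusters
        singleton = assignment.singleton_clusters[0]
        assert assignment.members(singleton) == [8]

    def test_reproducible(self, rng):
        rows = rng.random((12, 10))
        k1, a1 = choose_k(rows, ClusteringConfig(k=1), k_max=12)
        k2, a2 = choose_k(rows, ClusteringConfig(k=1), k_max=12)
        assert k1 == k2 and a1.labels == a2.labels

    def test_identical_rows_fall_back_with_warning(self):
        rows = np.tile(np.arange(6.0), (4, 1))
        with pytest.warns(UserWarning, match="singleton"):
            k, assignment = choose_k(rows, ClusteringConfig(k=1), k_max=3)
        assert k == 3
        assert not assignment.singleton_clusters


def oracle_average_linkage(dist):
    """Recompute every cluster-pair mean each step; ties to lowest leaf pair."""
    n = len(dist)
    clusters = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            avg = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            key = (avg, min(min(clusters[a]), min(clusters[b])),
                   max(min(clusters[a]), min(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _, _), a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), avg))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHierarchical:
    def test_forced_first_merge(self):
        # three profiles whose pairwise distances order the first merge
        rows = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.1, 2.0, 3.1, 4.0],  # nearly identical to row 0
                [4.0, 1.0, 3.5, 0.5],
            ]
        )
        d = hierarchical(rows)
        assert set(d.merges[0][:2]) == {0, 1}

    def test_identical_rows_merge_first_at_zero(self, rng):
        base = rng.random(10)
        rows = np.vstack([rng.random((2, 10)), base, base])
        d = hierarchical(rows)
        assert set(d.merges[0][:2]) == {2, 3}
        assert d.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        rows = rng.random((8, 15))
        dist = pairwise_correlation_distance(rows)
        expected = oracle_average_linkage(dist)
        d = hierarchical(rows)
        coph_members = {i: [i] for i in range(8)}
        for step, (a, b, h, size) in enumerate(d.merges):
            merged = sorted(coph_members[a] + coph_members[b])
            coph_members[8 + step] = merged
            assert merged == expected[step][0]
            assert h == pytest.approx(expected[step][1], abs=1e-10)
            assert size == len(merged)

    def test_heights_match_scipy_average_linkage(self, rng):
        rows = rng.random((10, 20))
        dist = pairwise_correlation_distance(rows)
        ours = sorted(hierarchical(rows).heights())
        scipy_heights = sorted(linkage(squareform(dist, checks=False), "average")[:, 2])
        assert np.allclose(ours, scipy_heights, atol=1e-10)

    def test_heights_non_decreasing(self, rng):
        for _ in range(5):
            rows = rng.random((9, 12))
            h = hierarchical(rows).heights()
            assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))

    def test_cophenetic_ultrametric(self, rng):
        rows = rng.random((7, 10))
        coph = hierarchical(rows).cophenetic_matrix()
        for i, j, k in itertools.permutations(range(7), 3):
            assert coph[i, j] <= max(coph[i, k], coph[k, j]) + 1e-12

    def test_single_row_rejected(self, rng):
        with pytest.raises(ValueError):
            hierarchical(rng.random((1, 5)))

    def test_newick_preserves_cophenetic_distances(self, rng):
        rows = rng.random((6, 12))
        labels = [f"GSM{i}" for i in range(6)]
        d = hierarchical(rows, labels=labels)
        tree = dendropy.Tree.get(data=d.to_newick(), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        coph = d.cophenetic_matrix()
        for i, j in itertools.combinations(range(6), 2):
            patristic = pdm.distance(taxa[f"GSM{i}"], taxa[f"GSM{j}"])
            assert patristic == pytest.approx(coph[i, j], abs=1e-4)
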