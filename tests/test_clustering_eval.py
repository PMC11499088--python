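"""Correlation distance, complete linkage, silhouette-k, AMI."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import adjusted_mutual_info_score

from morphodetail.clustering_eval import (ami, cluster_and_score,
                                          correlation_distance,
                                          expected_mutual_information,
                                          hierarchical_cluster, retain_pcs,
                                          silhouette_select_k)
from morphodetail.errors import UndefinedCorrelationError
from morphodetail.shape_model import CorrespondenceSet, fit_pca


class TestRetainPCs:
    def _model_with_eigenvalues(self, lam):
        """Tiny synthetic model whose spectrum is exactly *lam*."""
        from morphodetail.shape_model import ShapeModel
        lam = np.asarray(lam, dtype=float)
        m = len(lam)
        return ShapeModel(mean=np.zeros(3 * m), eigenvalues=lam,
                          eigenvectors=np.eye(3 * m)[:, :m],
                          scores=np.zeros((m + 1, m)), n_shapes=m + 1,
                          shape_ids=[f"s{i}" for i in range(m + 1)])

    def test_threshold_crossing(self):
        model = self._model_with_eigenvalues([0.6, 0.3, 0.1])
        assert retain_pcs(model, threshold=0.85) == 2

    def test_full_threshold_keeps_all_modes(self):
        model = self._model_with_eigenvalues([0.6, 0.3, 0.1])
        assert retain_pcs(model, threshold=1.0) == 3

    def test_reference_count_takes_precedence(self):
        model = self._model_with_eigenvalues(list(range(12, 0, -1)))
        assert retain_pcs(model, reference_n_modes=10) == 10


class TestCorrelationDistance:
    def test_identical_is_zero(self):
        u = np.array([1.0, 2.0, 5.0])
        assert correlation_distance(u, u) < 1e-12

    def test_anticorrelated_is_two(self):
        u = np.array([1.0, 2.0, 3.0])
        assert np.isclose(correlation_distance(u, -u), 2.0, atol=1e-12)

    def test_worked_example(self):
        # r((1,2,3),(1,3,2)) = 0.5, distance 0.5
        assert np.isclose(
            correlation_distance(np.array([1.0, 2.0, 3.0]),
                                 np.array([1.0, 3.0, 2.0])), 0.5, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation_distance(np.array([1.0, 1.0, 1.0]),
                                 np.array([1.0, 2.0, 3.0]))


def brute_force_complete_linkage(points):
    """Naive agglomeration: merge the pair of clusters with the smallest
    maximum pairwise correlation distance; returns the partition sequence."""
    n = len(points)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = correlation_distance(points[i], points[j])
    clusters = [{i} for i in range(n)]
    partitions = [[frozenset(c) for c in clusters]]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            key = (h, min(min(clusters[a]), min(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _), a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
        partitions.append([frozenset(c) for c in clusters])
    return partitions, heights


class TestHierarchicalCluster:
    def test_duplicate_rows_merge_first_at_zero(self, rng):
        x = rng.normal(size=(5, 4))
        x[3] = x[1]
        record = hierarchical_cluster(x)
        assert record[0, 2] < 1e-12
        assert {int(record[0, 0]), int(record[0, 1])} == {1, 3}

    def test_matches_brute_force_partitions(self, rng):
        """Dendrogram cuts reproduce naive agglomeration on small cohorts."""
        x = rng.normal(size=(9, 5))
        record = hierarchical_cluster(x)
        partitions, _ = brute_force_complete_linkage(x)
        for k in range(2, 9):
            labels = fcluster(record, k, criterion="maxclust")
            ours = {frozenset(np.flatnonzero(labels == c))
                    for c in np.unique(labels)}
            naive = {frozenset(c) for c in partitions[len(x) - k]}
            assert ours == naive

    def test_merge_heights_match_recomputed_max_distances(self, rng):
        x = rng.normal(size=(8, 5))
        record = hierarchical_cluster(x)
        _, heights = brute_force_complete_linkage(x)
        assert np.allclose(np.sort(record[:, 2]), np.sort(heights),
                           atol=1e-10)

    def test_monotone_merge_heights(self, rng):
        x = rng.normal(size=(12, 6))
        record = hierarchical_cluster(x)
        assert np.all(np.diff(record[:, 2]) >= -1e-12)

    def test_two_blob_structure_merges_within_blobs_first(self, rng):
        a = rng.normal(0, 0.05, size=(3, 4)) + np.array([1, 2, 3, 4.0])
        b = rng.normal(0, 0.05, size=(3, 4)) + np.array([4, 3, 2, 1.0])
        record = hierarchical_cluster(np.vstack([a, b]))
        labels = fcluster(record, 2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]


class TestSilhouetteSelectK:
    def _blobs(self, rng, centers, n_per=15, sd=0.1):
        return np.vstack([rng.normal(0, sd, size=(n_per, len(c))) + c
                          for c in centers])

    def test_two_well_separated_blobs(self, rng):
        x = self._blobs(rng, [[10, 0, 0, 5], [0, 10, 5, 0]])
        record = hierarchical_cluster(x)
        k, s = silhouette_select_k(x, record)
        assert k == 2
        assert s > 0.8

    def test_three_blobs(self, rng):
        x = self._blobs(rng, [[10, 0, 0, 5], [0, 10, 5, 0], [5, 5, 10, -5]])
        record = hierarchical_cluster(x)
        k, _ = silhouette_select_k(x, record)
        assert k == 3

    def test_k_min_below_two_rejected(self, rng):
        x = rng.normal(size=(10, 4))
        record = hierarchical_cluster(x)
        with pytest.raises(ValueError):
            silhouette_select_k(x, record, k_min=1)


class TestAMI:
    def brute_force_emi(self, table):
        """Direct hypergeometric sum with exact integer factorials."""
        from math import comb, log
        a = table.sum(axis=1)
        b = table.sum(axis=0)
        n = int(table.sum())
        emi = 0.0
        for ai in a:
            for bj in b:
                for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                    p = (comb(bj, nij) * comb(n - bj, ai - nij)) / comb(n, ai)
                    emi += p * nij / n * log(n * nij / (ai * bj))
        return emi

    def test_emi_matches_brute_force_on_random_tables(self, rng):
        for _ in range(10):
            table = rng.integers(0, 8, size=(4, 4))
            table[0, 0] += 1  # nonzero total
            assert np.isclose(expected_mutual_information(table),
                              self.brute_force_emi(table), atol=1e-10)

    def test_self_agreement_is_one(self, rng):
        u = rng.integers(0, 3, 40)
        assert np.isclose(ami(u, u), 1.0, atol=1e-12)

    def test_label_permutation_invariance(self, rng):
        u = rng.integers(0, 3, 40)
        renamed = np.array(["xyz"[i] for i in u])
        assert np.isclose(ami(u, renamed), 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        u = rng.integers(0, 3, 50)
        v = rng.integers(0, 4, 50)
        assert ami(u, v) == ami(v, u)

    def test_chance_level_for_independent_labels(self):
        values = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            values.append(ami(r.integers(0, 2, 1000), r.integers(0, 2, 1000)))
        assert max(abs(v) for v in values) < 0.05

    def test_matches_sklearn(self, rng):
        for _ in range(5):
            u = rng.integers(0, 4, 60)
            v = rng.integers(0, 3, 60)
            assert np.isclose(ami(u, v), adjusted_mutual_info_score(u, v),
                              atol=1e-12)

    def test_single_class_conventions(self):
        ones = np.ones(10)
        assert ami(ones, ones) == 1.0
        mixed = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        assert ami(ones, mixed) == 0.0

    def test_ami_never_exceeds_one(self, rng):
        for _ in range(20):
            u = rng.integers(0, 3, 30)
            v = rng.integers(0, 3, 30)
            assert ami(u, v) <= 1.0 + 1e-12


class TestClusterAndScore:
    def _separable_model(self, rng, n=20):
        """Correspondences whose first mode separates two classes."""
        labels = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        base = rng.normal(size=(1, 30))
        direction = rng.normal(size=(1, 30))
        offsets = np.where(labels == "A", 4.0, -4.0)[:, None]
        x = base + offsets * direction + rng.normal(0, 0.2, size=(n, 30))
        corr = CorrespondenceSet(points=x.reshape(n, 10, 3),
                                 shape_ids=[f"s{i}" for i in range(n)])
        return fit_pca(corr), labels

    def test_recovers_separable_classes_with_perfect_ami(self, rng):
        model, labels = self._separable_model(rng)
        result = cluster_and_score(model, labels)
        assert result.k == 2
        assert np.isclose(result.ami_score, 1.0, atol=1e-9)
        assert sorted(result.cluster_sizes) == [10, 10]

    def test_stability_flag_for_clean_structure(self, rng):
        model, labels = self._separable_model(rng)
        result = cluster_and_score(model, labels)
        assert result.stable_across_thresholds

    def test_label_count_mismatch_rejected(self, rng):
        model, labels = self._separable_model(rng)
        with pytest.raises(ValueError):
            cluster_and_score(model, labels[:-1])

    def test_serialization(self, rng, tmp_path):
        model, labels = self._separable_model(rng)
        result = cluster_and_score(model, labels)
        path = tmp_path / "clustering.json"
        result.save(path)
        import json
        data = json.loads(path.read_text())
        assert data["k"] == result.k
        assert np.isclose(data["ami"], result.ami_score)
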