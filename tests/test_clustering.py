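"""Distance computation, the two hierarchical algorithms, and the ensemble.

The agglomerative and DIANA implementations are checked two ways: against
naive step-by-step reference implementations written independently in this
file, and against frozen partitions computed with R's ``stats::hclust``
(average linkage) and ``cluster::diana`` on seeded random instances.
"""

import numpy as np
import pytest

from atrophyclust import (
    ConsensusParams,
    DistanceMatrix,
    adjusted_rand,
    agglomerative_cluster,
    consensus_ensemble,
    diana_cluster,
    manhattan_distance,
)

from conftest import make_blobs


# ---------------------------------------------------------------- references

def brute_force_average_linkage(d: np.ndarray, K: int) -> np.ndarray:
    """Naive O(n^3) average-linkage agglomeration (merge closest pair)."""
    clusters = [[i] for i in range(len(d))]
    while len(clusters) > K:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = d[np.ix_(clusters[i], clusters[j])].mean()
                if best is None or avg < best[0]:
                    best = (avg, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(d), dtype=int)
    for ci, c in enumerate(clusters, start=1):
        labels[c] = ci
    return labels


def reference_diana(d: np.ndarray, K: int) -> np.ndarray:
    """Literal transcription of the divisive-analysis splinter procedure."""
    def avg_to(i, group):
        grp = [g for g in group if g != i]
        return d[i, grp].mean() if grp else 0.0

    clusters = [list(range(len(d)))]
    while len(clusters) < K:
        diams = [d[np.ix_(c, c)].max() if len(c) > 1 else -1 for c in clusters]
        ci = int(np.argmax(diams))
        cluster = clusters[ci]
        averages = np.array([avg_to(i, cluster) for i in cluster])
        splinter = [cluster[int(np.argmax(averages))]]
        rest = [i for i in cluster if i not in splinter]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            gains = [avg_to(i, rest) - d[i, splinter].mean() for i in rest]
            best = int(np.argmax(gains))
            if gains[best] > 1e-15:
                splinter.append(rest.pop(best))
                moved = True
        clusters[ci : ci + 1] = [sorted(splinter), sorted(rest)]
    labels = np.empty(len(d), dtype=int)
    for ci, c in enumerate(clusters, start=1):
        labels[c] = ci
    return labels


def random_instance(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    return np.abs(pts[:, None, :] - pts[None, :, :]).sum(-1)


# frozen partitions from R (stats::hclust average / cluster::diana) on the
# distance matrices returned by random_instance(seed, n); one list per K
# running K = 2 .. n-1
R_REFERENCE_PARTITIONS = [
    (101, 6, "diana", [[1, 2, 2, 2, 1, 1], [1, 2, 2, 2, 3, 3],
                       [1, 2, 3, 2, 4, 4], [1, 2, 3, 2, 4, 5]]),
    (101, 6, "hc", [[1, 2, 2, 2, 1, 1], [1, 2, 2, 2, 3, 3],
                    [1, 2, 3, 2, 4, 4], [1, 2, 3, 2, 4, 5]]),
    (202, 7, "diana", [[1, 2, 2, 2, 2, 1, 2], [1, 2, 3, 2, 2, 1, 3],
                       [1, 2, 3, 2, 4, 1, 3], [1, 2, 3, 2, 4, 5, 3],
                       [1, 2, 3, 4, 5, 6, 3]]),
    (202, 7, "hc", [[1, 2, 2, 2, 2, 1, 2], [1, 2, 3, 2, 2, 1, 3],
                    [1, 2, 3, 2, 2, 4, 3], [1, 2, 3, 2, 4, 5, 3],
                    [1, 2, 3, 4, 5, 6, 3]]),
    (303, 8, "diana", [[1, 2, 1, 2, 2, 1, 2, 2], [1, 2, 1, 2, 3, 1, 2, 2],
                       [1, 2, 1, 2, 3, 4, 2, 2], [1, 2, 1, 2, 3, 4, 5, 5],
                       [1, 2, 1, 2, 3, 4, 5, 6], [1, 2, 3, 2, 4, 5, 6, 7]]),
    (303, 8, "hc", [[1, 1, 1, 1, 2, 1, 1, 1], [1, 1, 1, 1, 2, 3, 1, 1],
                    [1, 2, 1, 2, 3, 4, 2, 2], [1, 2, 1, 2, 3, 4, 5, 5],
                    [1, 2, 1, 2, 3, 4, 5, 6], [1, 2, 3, 2, 4, 5, 6, 7]]),
]


# ------------------------------------------------------------------ distance

class TestManhattanDistance:
    def test_identical_rows_have_zero_distance(self):
        d = manhattan_distance(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.d[0, 1] == 0.0

    def test_definition_arithmetic(self):
        d = manhattan_distance(np.array([[1.0, 2.0, 3.0], [2.0, 0.0, 3.0]]))
        assert d.d[0, 1] == 3.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        d = manhattan_distance(X).d
        for i in range(20):
            for j in range(20):
                expected = sum(abs(X[i, k] - X[j, k]) for k in range(5))
                assert abs(d[i, j] - expected) < 1e-12

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        d = manhattan_distance(rng.normal(size=(30, 4))).d
        for _ in range(200):
            i, j, k = rng.integers(0, 30, 3)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_nonfinite_scores_rejected_with_subject_list(self):
        X = np.ones((4, 2))
        X[2, 0] = np.nan
        with pytest.raises(ValueError, match=r"\[2\]"):
            manhattan_distance(X)


# ---------------------------------------------------------------- algorithms

def _dm(points_1d):
    x = np.asarray(points_1d, float)[:, None]
    return manhattan_distance(x)


class TestAgglomerative:
    def test_separated_blobs(self):
        labels = agglomerative_cluster(_dm([0, 1, 10, 11]), 2).labels
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])

    def test_k_equals_n_gives_singletons(self):
        labels = agglomerative_cluster(_dm([0, 1, 10, 11]), 4).labels
        np.testing.assert_array_equal(labels, [1, 2, 3, 4])

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            agglomerative_cluster(_dm([0, 1]), 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reference(self, seed):
        d = random_instance(seed + 400, 7)
        for K in range(2, 7):
            mine = agglomerative_cluster(DistanceMatrix(d), K).labels
            ref = brute_force_average_linkage(d, K)
            assert adjusted_rand(mine, ref) == 1.0


class TestDiana:
    def test_separated_blobs(self):
        labels = diana_cluster(_dm([0, 1, 10, 11]), 2).labels
        np.testing.assert_array_equal(labels, [1, 1, 2, 2])

    def test_hand_constructed_split_sequence(self):
        """5-point matrix where the trace is checkable by hand: object 0 has
        the largest average dissimilarity, object 1 follows it into the
        splinter group, and the rest stay."""
        d = np.array(
            [
                [0, 2, 6, 10, 9],
                [2, 0, 5, 9, 8],
                [6, 5, 0, 4, 5],
                [10, 9, 4, 0, 3],
                [9, 8, 5, 3, 0],
            ],
            float,
        )
        labels = diana_cluster(DistanceMatrix(d), 2).labels
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 2])
        labels3 = diana_cluster(DistanceMatrix(d), 3).labels
        np.testing.assert_array_equal(labels3, [1, 1, 2, 3, 3])

    def test_all_equal_distances_tie_breaks_to_lowest_index(self):
        d = np.ones((5, 5)) - np.eye(5)
        labels = diana_cluster(DistanceMatrix(d), 2).labels
        np.testing.assert_array_equal(labels, [1, 2, 2, 2, 2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_trace(self, seed):
        d = random_instance(seed + 500, 8)
        for K in range(2, 8):
            mine = diana_cluster(DistanceMatrix(d), K).labels
            ref = reference_diana(d, K)
            assert adjusted_rand(mine, ref) == 1.0

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diana_cluster(_dm([0, 1]), 5)


@pytest.mark.parametrize("seed,n,alg,partitions", R_REFERENCE_PARTITIONS)
def test_partitions_match_r_cluster_package(seed, n, alg, partitions):
    """Frozen cross-check against R stats::hclust / cluster::diana."""
    d = DistanceMatrix(random_instance(seed, n))
    fn = diana_cluster if alg == "diana" else agglomerative_cluster
    for K, expected in zip(range(2, n), partitions):
        assert adjusted_rand(fn(d, K).labels, np.array(expected)) == 1.0


# ------------------------------------------------------------------ ensemble

class TestConsensusEnsemble:
    def test_separable_blobs_recovered_exactly(self):
        X, y = make_blobs(np.eye(3) * 20, n_per=10, sd=0.5, seed=0)
        res = consensus_ensemble(X, 3, ConsensusParams(seed=1))
        assert adjusted_rand(res.final.labels, y) == 1.0

    def test_consensus_matrix_is_binary_on_separable_blobs(self):
        X, y = make_blobs(np.eye(3) * 20, n_per=10, sd=0.5, seed=0)
        res = consensus_ensemble(X, 3, ConsensusParams(seed=1))
        same = y[:, None] == y[None, :]
        sampled = res.cosample_counts > 0
        np.testing.assert_array_equal(
            res.consensus_matrix[same & sampled], 1.0
        )
        assert np.all(res.consensus_matrix[~same & sampled] == 0.0)

    def test_counts_are_valid_frequencies(self):
        X, _ = make_blobs(np.eye(2) * 5, n_per=8, sd=1.0, seed=2)
        res = consensus_ensemble(X, 2, ConsensusParams(seed=3))
        assert np.all(res.cocluster_counts <= res.cosample_counts)
        assert np.all(res.cocluster_counts == res.cocluster_counts.astype(int))
        off = ~np.eye(len(X), dtype=bool)
        vals = res.consensus_matrix[off & (res.cosample_counts > 0)]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.diag(res.consensus_matrix) == 1.0)

    def test_full_sample_single_algorithm_reduces_to_that_algorithm(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 4))
        params = ConsensusParams(subsample_frac=1.0, reps=3,
                                 algorithms=("diana",), seed=5)
        res = consensus_ensemble(X, 3, params)
        direct = diana_cluster(manhattan_distance(X), 3)
        assert adjusted_rand(res.final.labels, direct.labels) == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        a = consensus_ensemble(X, 2, ConsensusParams(seed=7))
        b = consensus_ensemble(X, 2, ConsensusParams(seed=7))
        np.testing.assert_array_equal(a.final.labels, b.final.labels)
        np.testing.assert_array_equal(a.consensus_matrix, b.consensus_matrix)

    def test_subject_permutation_invariance_at_full_sampling(self):
        """With every replicate seeing the whole cohort, reordering the
        subjects must permute the partition correspondingly."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        perm = rng.permutation(20)
        # a single algorithm keeps the consensus matrix binary, so the recut
        # has no ties and the invariance is exact
        params = ConsensusParams(subsample_frac=1.0, reps=2,
                                 algorithms=("diana",), seed=9)
        a = consensus_ensemble(X, 3, params).final.labels
        b = consensus_ensemble(X[perm], 3, params).final.labels
        assert adjusted_rand(a[perm], b) == 1.0

    def test_final_labels_are_canonicalized(self):
        X, _ = make_blobs(np.eye(3) * 15, n_per=7, sd=0.4, seed=10)
        res = consensus_ensemble(X, 3, ConsensusParams(seed=11))
        first_seen = []
        for lab in res.final.labels:
            if lab not in first_seen:
                first_seen.append(lab)
        assert first_seen == sorted(first_seen)

    def test_invalid_params_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            consensus_ensemble(X, 1, ConsensusParams(seed=0))
        with pytest.raises(ValueError):
            consensus_ensemble(X, 2, ConsensusParams(subsample_frac=0.0))
        with pytest.raises(ValueError):
            consensus_ensemble(X, 2, ConsensusParams(algorithms=("kmeans",)))
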