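"""Hierarchical clustering algorithms and the subsample consensus ensemble.

Two hierarchical algorithms operate on a Manhattan distance matrix over
principal-component scores: bottom-up agglomerative clustering (average
linkage by default) and top-down DIANA (DIvisive ANAlysis), which
repeatedly splits the cluster of largest diameter by growing a "splinter"
subgroup.  The consensus ensemble re-runs both algorithms on seeded 80%
subsamples, accumulates a co-clustering frequency matrix over co-sampled
pairs, and recuts (1 - consensus) agglomeratively into the final partition.

All tie-breaks resolve to the lowest subject index, so results are
platform-independent for a given seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .dimred import PCScores

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "ConsensusParams",
    "ConsensusResult",
    "manhattan_distance",
    "agglomerative_cluster",
    "diana_cluster",
    "consensus_ensemble",
]


@dataclass
class DistanceMatrix:
    d: np.ndarray
    metric_name: str = "manhattan"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(self.d[np.ix_(idx, idx)], self.metric_name)


@dataclass
class ClusterAssignment:
    """Labels in 1..K, canonicalized by order of first subject occurrence."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.K:
            raise ValueError("labels must lie in 1..K")


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels so cluster numbers follow first-occurrence order."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out


def manhattan_distance(scores: PCScores | np.ndarray) -> DistanceMatrix:
    """Pairwise L1 (city-block) distances between subjects' score rows."""
    X = scores.scores if isinstance(scores, PCScores) else np.asarray(scores, float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D score matrix with >= 1 column")
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite scores for subject(s) {bad.tolist()}")
    d = cdist(X, X, metric="cityblock")
    d = (d + d.T) / 2.0  # guard against last-bit asymmetry
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d)


def agglomerative_cluster(
    d: DistanceMatrix, K: int, linkage: str = "average"
) -> ClusterAssignment:
    """Bottom-up hierarchical clustering; the tree is cut at exactly K."""
    n = d.n
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in 1..{n}, got {K}")
    if K == n:
        return ClusterAssignment(np.arange(1, n + 1), K)
    Z = hierarchy.linkage(squareform(d.d, checks=False), method=linkage)
    labels = hierarchy.cut_tree(Z, n_clusters=K).ravel()
    return ClusterAssignment(canonicalize_labels(labels), K)


def _avg_dissim(d: np.ndarray, i: int, group: list[int]) -> float:
    others = [j for j in group if j != i]
    if not others:
        return 0.0
    return float(d[i, others].mean())


def _diana_split(d: np.ndarray, cluster: list[int]) -> tuple[list[int], list[int]]:
    """One DIANA division: grow a splinter group from the most dissimilar
    object, moving objects while any is closer (on average) to the splinter.
    Ties resolve to the lowest index."""
    # splinter seed: maximal average dissimilarity to the rest
    avg = [(-_avg_dissim(d, i, cluster), i) for i in cluster]
    seed = min(avg)[1]  # most dissimilar; lowest index on ties
    splinter = [seed]
    remaining = [i for i in cluster if i != seed]
    while len(remaining) > 1:
        best_gain, best_obj = 0.0, None
        for i in remaining:
            a = _avg_dissim(d, i, remaining)
            b = float(d[i, splinter].mean())
            gain = a - b
            if gain > best_gain + 1e-15:
                best_gain, best_obj = gain, i
        if best_obj is None:
            break
        splinter.append(best_obj)
        remaining.remove(best_obj)
    return sorted(splinter), sorted(remaining)


def diana_cluster(d: DistanceMatrix, K: int) -> ClusterAssignment:
    """DIvisive ANAlysis clustering cut at K clusters.

    Starting from a single all-inclusive cluster, the cluster of largest
    diameter is repeatedly divided by the splinter procedure until K
    clusters exist.
    """
    n = d.n
    if not 1 <= K <= n:
        raise ValueError(f"K must lie in 1..{n}, got {K}")
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < K:
        diameters = [
            (max((d.d[np.ix_(c, c)]).max(), 0.0) if len(c) > 1 else -1.0, ci)
            for ci, c in enumerate(clusters)
        ]
        diam, ci = max(diameters, key=lambda t: (t[0], -t[1]))
        if diam <= 0.0:
            # only singletons or zero-diameter clusters left: split the
            # lowest-index multi-member cluster by peeling its first object
            multi = [i for i, c in enumerate(clusters) if len(c) > 1]
            if not multi:
                raise ValueError(f"cannot form {K} clusters from {n} objects")
            c = clusters.pop(multi[0])
            clusters.insert(multi[0], [c[0]])
            clusters.insert(multi[0] + 1, c[1:])
            continue
        c = clusters.pop(ci)
        a, b = _diana_split(d.d, c)
        clusters.insert(ci, a)
        clusters.insert(ci + 1, b)
    labels = np.empty(n, dtype=int)
    for ci, c in enumerate(clusters, start=1):
        labels[c] = ci
    return ClusterAssignment(canonicalize_labels(labels), K)


_ALGORITHMS = {
    "hc": lambda d, K, linkage: agglomerative_cluster(d, K, linkage),
    "diana": lambda d, K, linkage: diana_cluster(d, K),
}


@dataclass
class ConsensusParams:
    subsample_frac: float = 0.8
    reps: int = 10
    algorithms: tuple[str, ...] = ("hc", "diana")
    linkage: str = "average"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ValueError("subsample_frac must lie in (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = [a for a in self.algorithms if a not in _ALGORITHMS]
        if unknown:
            raise ValueError(f"unknown algorithm(s): {unknown}")


@dataclass
class ReplicateAssignment:
    algorithm: str
    replicate: int
    subsample: np.ndarray       # subject indices, sorted
    labels: np.ndarray          # labels over the subsample


@dataclass
class ConsensusResult:
    replicate_assignments: list[ReplicateAssignment]
    consensus_matrix: np.ndarray
    cosample_counts: np.ndarray
    cocluster_counts: np.ndarray
    final: ClusterAssignment
    params: ConsensusParams
    K: int


def consensus_ensemble(
    scores: PCScores | np.ndarray,
    K: int,
    params: ConsensusParams | None = None,
) -> ConsensusResult:
    """Diverse-ensemble consensus clustering on subsampled cohorts.

    Each replicate draws ``ceil(subsample_frac * n)`` subjects without
    replacement (both algorithms see the same subsample) and clusters them
    at K.  The consensus matrix is the co-clustering frequency among
    co-sampled pairs; the final partition is an average-linkage recut of
    (1 - consensus) at K.  Pairs that were never co-sampled receive an
    uninformative 0.5 consensus; a subject never co-sampled with anyone is
    excluded from the recut and imputed from its nearest neighbour in score
    space.
    """
    params = params or ConsensusParams()
    params.validate()
    if K < 2:
        raise ValueError("K must be >= 2")
    X = scores.scores if isinstance(scores, PCScores) else np.asarray(scores, float)
    n = X.shape[0]
    dist = manhattan_distance(X)
    rng = np.random.default_rng(params.seed)
    size = math.ceil(params.subsample_frac * n)

    cocluster = np.zeros((n, n))
    cosample = np.zeros((n, n))
    replicates: list[ReplicateAssignment] = []
    for rep in range(params.reps):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub = dist.submatrix(idx)
        for alg in params.algorithms:
            assign = _ALGORITHMS[alg](sub, min(K, size), params.linkage)
            if assign.labels.max() < K:
                warnings.warn(
                    f"replicate {rep} ({alg}) produced "
                    f"{assign.labels.max()} < {K} clusters; retained",
                    stacklevel=2,
                )
            replicates.append(
                ReplicateAssignment(alg, rep, idx, assign.labels)
            )
            same = assign.labels[:, None] == assign.labels[None, :]
            cocluster[np.ix_(idx, idx)] += same
            cosample[np.ix_(idx, idx)] += 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = cocluster / cosample
    never = cosample == 0
    consensus[never] = 0.5
    np.fill_diagonal(consensus, 1.0)

    # subjects with no co-sampled peer at all: impute after the recut
    off_cosample = cosample.copy()
    np.fill_diagonal(off_cosample, 0.0)
    isolated = np.flatnonzero(off_cosample.sum(axis=1) == 0)
    included = np.setdiff1d(np.arange(n), isolated)
    cons_dist = DistanceMatrix(
        np.clip(1.0 - consensus[np.ix_(included, included)], 0.0, 1.0),
        "one_minus_consensus",
    )
    sub_final = agglomerative_cluster(cons_dist, min(K, len(included)),
                                      params.linkage)
    labels = np.zeros(n, dtype=int)
    labels[included] = sub_final.labels
    for i in isolated:
        order = np.argsort(dist.d[i, included], kind="stable")
        labels[i] = labels[included[order[0]]]
    final = ClusterAssignment(canonicalize_labels(labels), K)
    return ConsensusResult(
        replicate_assignments=replicates,
        consensus_matrix=consensus,
        cosample_counts=cosample,
        cocluster_counts=cocluster,
        final=final,
        params=params,
        K=K,
    )
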