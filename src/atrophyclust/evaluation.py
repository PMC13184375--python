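"""Cluster-number selection and partition-stability metrics.

Implements the Calinski–Harabasz index for evaluating cluster separation in
principal-component space, pair-counting agreement between partitions
(Rand index and its chance-corrected adjusted form), and a leave-one-out
stability analysis that re-runs the full consensus ensemble with each
subject withheld.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    ClusterAssignment,
    ConsensusParams,
    ConsensusResult,
    consensus_ensemble,
)
from .dimred import PCScores

__all__ = [
    "calinski_harabasz",
    "rand_index",
    "adjusted_rand",
    "StabilityReport",
    "loo_stability",
    "select_k",
]


def _score_matrix(scores: PCScores | np.ndarray) -> np.ndarray:
    return scores.scores if isinstance(scores, PCScores) else np.asarray(scores, float)


def calinski_harabasz(
    scores: PCScores | np.ndarray, assignment: ClusterAssignment | np.ndarray
) -> float:
    """Calinski–Harabasz index: CH = (B/(K-1)) / (W/(n-K)).

    B is the between-cluster dispersion ``sum_k n_k ||mu_k - mu||^2`` and W
    the pooled within-cluster dispersion, both Euclidean in component-score
    space.  A perfectly tight clustering (W = 0) returns ``inf`` with a
    warning.
    """
    X = _score_matrix(scores)
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment)
        else np.asarray(assignment, dtype=int)
    )
    n = X.shape[0]
    uniq = np.unique(labels)
    K = len(uniq)
    if K < 2:
        raise ValueError("need at least 2 clusters")
    if K >= n:
        raise ValueError("need K < n")
    mu = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for lab in uniq:
        Xi = X[labels == lab]
        mu_k = Xi.mean(axis=0)
        B += len(Xi) * float(np.sum((mu_k - mu) ** 2))
        W += float(np.sum((Xi - mu_k) ** 2))
    if W == 0.0:
        warnings.warn(
            "zero within-cluster dispersion: CH index is infinite",
            stacklevel=2,
        )
        return float("inf")
    return (B / (K - 1)) / (W / (n - K))


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def _labels(x) -> np.ndarray:
    return x.labels if isinstance(x, ClusterAssignment) else np.asarray(x)


def rand_index(a, b) -> float:
    """Rand index: fraction of subject pairs on which two partitions agree."""
    la, lb = _labels(a), _labels(b)
    if len(la) != len(lb):
        raise ValueError("partitions must cover the same subjects")
    n = len(la)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = _contingency(la, lb)
    nij2 = np.sum(t * (t - 1)) / 2
    ai = t.sum(axis=1)
    bj = t.sum(axis=0)
    a2 = np.sum(ai * (ai - 1)) / 2
    b2 = np.sum(bj * (bj - 1)) / 2
    total = n * (n - 1) / 2
    # agreements = pairs together in both + pairs apart in both
    return float((total + 2 * nij2 - a2 - b2) / total)


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index via the contingency-table formula (chance-
    corrected; 0 expected for independent partitions, 1 for identity)."""
    la, lb = _labels(a), _labels(b)
    if len(la) != len(lb):
        raise ValueError("partitions must cover the same subjects")
    n = len(la)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = _contingency(la, lb)
    nij2 = np.sum(t * (t - 1)) / 2
    ai = t.sum(axis=1)
    bj = t.sum(axis=0)
    a2 = np.sum(ai * (ai - 1)) / 2
    b2 = np.sum(bj * (bj - 1)) / 2
    total = n * (n - 1) / 2
    expected = a2 * b2 / total
    maximum = (a2 + b2) / 2
    if maximum == expected:
        # both partitions trivial (all-singletons or all-together)
        return 1.0 if nij2 == expected else 0.0
    return float((nij2 - expected) / (maximum - expected))


@dataclass
class StabilityReport:
    """Leave-one-out agreement with the full-cohort partition.

    ``per_fold`` has one row per withheld subject with the Rand and adjusted
    Rand index between the fold's partition and the full-cohort partition
    restricted to the shared subjects.  The summary reports the median and
    interquartile range of each metric.
    """

    per_fold: pd.DataFrame
    summary: dict
    K: int
    params: ConsensusParams
    failures: list = field(default_factory=list)


def loo_stability(
    scores: PCScores | np.ndarray,
    K: int,
    params: ConsensusParams | None = None,
    full_result: ConsensusResult | None = None,
) -> StabilityReport:
    """Leave-one-out stability of the consensus partition.

    For every subject the consensus ensemble is re-run on the other n-1
    subjects with a fold-specific seed stream derived from the root seed,
    and compared with the full-cohort assignment on the shared subjects.
    Folds that fail are recorded and skipped.
    """
    params = params or ConsensusParams()
    X = _score_matrix(scores)
    n = X.shape[0]
    if n < K + 2:
        raise ValueError(f"need at least K + 2 = {K + 2} subjects")
    if full_result is None:
        full_result = consensus_ensemble(X, K, params)
    full_labels = full_result.final.labels
    rows = []
    failures = []
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        fold_seed = int(
            np.random.SeedSequence(params.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        fold_params = ConsensusParams(
            subsample_frac=params.subsample_frac,
            reps=params.reps,
            algorithms=params.algorithms,
            linkage=params.linkage,
            seed=fold_seed,
        )
        try:
            res = consensus_ensemble(X[keep], K, fold_params)
        except Exception as exc:  # propagate per-fold, continue others
            failures.append((i, repr(exc)))
            continue
        rows.append(
            {
                "fold": i,
                "rand": rand_index(res.final.labels, full_labels[keep]),
                "adjusted_rand": adjusted_rand(
                    res.final.labels, full_labels[keep]
                ),
            }
        )
    per_fold = pd.DataFrame(rows)
    summary = {}
    for metric in ("rand", "adjusted_rand"):
        v = per_fold[metric].to_numpy()
        summary[metric] = {
            "median": float(np.median(v)),
            "iqr": (
                float(np.percentile(v, 25)),
                float(np.percentile(v, 75)),
            ),
        }
    return StabilityReport(per_fold, summary, K, params, failures)


def select_k(
    scores: PCScores | np.ndarray,
    k_candidates: tuple[int, ...] = (2, 3, 4),
    params: ConsensusParams | None = None,
) -> pd.DataFrame:
    """Run the full ensemble and CH index for each candidate K.

    Returns a table with one row per K carrying the CH index, the final
    assignment and a flag on the CH-maximal row.  The function reports and
    never silently picks: the index is one line of evidence, and a user may
    prefer a different K on substantive grounds.
    """
    params = params or ConsensusParams()
    if any(k < 2 for k in k_candidates):
        raise ValueError("every candidate K must be >= 2")
    X = _score_matrix(scores)
    rows = []
    for K in k_candidates:
        res = consensus_ensemble(X, K, params)
        rows.append(
            {
                "K": K,
                "ch_index": calinski_harabasz(X, res.final),
                "assignment": res.final,
                "result": res,
            }
        )
    table = pd.DataFrame(rows)
    best = int(table["ch_index"].idxmax())
    table["ch_maximal"] = False
    table.loc[best, "ch_maximal"] = True
    return table
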