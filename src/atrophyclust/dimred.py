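"""Sampling-adequacy check (KMO) and PCA reduction of w-score matrices.

The Kaiser–Meyer–Olkin index compares zero-order correlations with partial
correlations: values near 1 indicate shared variance that a component
analysis can compress; values near 0 indicate the correlation structure is
mostly pairwise-specific.  PCA is computed through the thin SVD of the
centred data matrix, which is the dual (Gram-matrix) route whenever there
are far more voxels than subjects and costs only O(n^2 V) memory/time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .maps import SubjectMaps

__all__ = ["PCScores", "kmo_index", "kmo_from_correlation", "reduce_maps"]


@dataclass
class PCScores:
    """Retained principal components of a subjects x voxels matrix.

    ``scores`` (n x m) are the patient-specific component scores;
    ``loadings`` (m x voxels) the spatial patterns; reconstruction is
    ``scores @ loadings + centering_vector``.  ``explained_fraction`` is the
    fraction of total variance per retained component, non-increasing.
    """

    scores: np.ndarray
    explained_fraction: np.ndarray
    loadings: np.ndarray
    centering_vector: np.ndarray
    subject_ids: list[str]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    def select(self, rows: np.ndarray) -> "PCScores":
        rows = np.asarray(rows)
        return PCScores(
            self.scores[rows],
            self.explained_fraction,
            self.loadings,
            self.centering_vector,
            [self.subject_ids[i] for i in rows],
        )


def kmo_from_correlation(R: np.ndarray) -> float:
    """Overall KMO computed directly from a correlation matrix.

    KMO = sum(r_ij^2) / (sum(r_ij^2) + sum(q_ij^2)) over off-diagonal pairs,
    where q are the partial correlations obtained from the inverse (or, for
    a singular matrix, pseudo-inverse, with a warning) of R.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or p < 3:
        raise ValueError("need a square correlation matrix with >= 3 variables")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular correlation matrix; using pseudo-inverse for partial "
            "correlations", stacklevel=2,
        )
        Rinv = np.linalg.pinv(R)
    d = np.sqrt(np.abs(np.diag(Rinv)))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    if r2 + q2 == 0.0:
        warnings.warn(
            "all correlations zero: KMO undefined (0/0), returning 0 — "
            "component analysis is not useful here", stacklevel=2,
        )
        return 0.0
    return float(r2 / (r2 + q2))


def kmo_index(matrix: np.ndarray) -> float:
    """Overall KMO sampling-adequacy index of a subjects x variables matrix.

    Raises on constant variables (their correlation is undefined).  When
    there are at least as many variables as subjects the correlation matrix
    is singular and the partial correlations fall back to a pseudo-inverse
    with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 variables")
    sd = X.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"constant variable(s) at column(s) {const.tolist()[:10]}: "
            "correlation undefined"
        )
    R = np.corrcoef(X, rowvar=False)
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            f"{X.shape[1]} variables >= {X.shape[0]} subjects: correlation "
            "matrix singular, using pseudo-inverse partial correlations",
            stacklevel=2,
        )
        Rinv = np.linalg.pinv(R)
        d = np.sqrt(np.abs(np.diag(Rinv)))
        with np.errstate(invalid="ignore", divide="ignore"):
            Q = -Rinv / np.outer(d, d)
        Q[~np.isfinite(Q)] = 0.0
        off = ~np.eye(R.shape[0], dtype=bool)
        r2 = np.sum(R[off] ** 2)
        q2 = np.sum(Q[off] ** 2)
        return float(r2 / (r2 + q2)) if (r2 + q2) else 0.0
    return kmo_from_correlation(R)


def kmo_voxel_subsample(
    maps: SubjectMaps, n_variables: int = 500, seed: int = 0
) -> float:
    """KMO on a seeded random subsample of voxel columns.

    Computing KMO on every voxel would require inverting a voxels x voxels
    correlation matrix; a fixed random subset of columns (near-constant
    columns excluded) gives a tractable estimate of the same adequacy.
    """
    rng = np.random.default_rng(seed)
    sd = maps.values.std(axis=0)
    candidates = np.flatnonzero(sd > 1e-12)
    if candidates.size < 3:
        raise ValueError("fewer than 3 non-constant voxels available for KMO")
    take = min(n_variables, candidates.size)
    cols = np.sort(rng.choice(candidates, size=take, replace=False))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kmo_index(maps.values[:, cols])


def reduce_maps(
    wscores: SubjectMaps | np.ndarray,
    min_var_frac: float = 0.01,
    max_components: int | None = None,
) -> PCScores:
    """Column-mean-centred PCA keeping components explaining >= min_var_frac.

    The thin SVD of the centred matrix is used, which is equivalent to the
    eigendecomposition of the subjects x subjects Gram matrix and never
    forms a voxels x voxels covariance.  Loadings are sign-fixed so each
    component's largest-magnitude loading is positive, making outputs
    deterministic across platforms.
    """
    if not 0.0 < min_var_frac < 1.0:
        raise ValueError("min_var_frac must lie in (0, 1)")
    if isinstance(wscores, SubjectMaps):
        X = wscores.values
        ids = list(wscores.subject_ids)
    else:
        X = np.asarray(wscores, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 subjects for PCA")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total == 0.0:
        raise ValueError("input matrix has zero variance")
    frac = ev / total
    keep = frac >= min_var_frac
    if max_components is not None:
        keep &= np.arange(len(frac)) < max_components
    m = int(keep.sum())
    if m == 0:
        raise ValueError(
            f"no component explains >= {min_var_frac:.2%} of the variance"
        )
    U, s, Vt, frac = U[:, :m], s[:m], Vt[:m], frac[:m]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(m):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return PCScores(
        scores=U * s,
        explained_fraction=frac,
        loadings=Vt,
        centering_vector=center,
        subject_ids=ids,
    )
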