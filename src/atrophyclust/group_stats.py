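"""Cluster characterization: atrophy contrasts, clinical profiles, composition.

``voxelwise_contrast`` fits a mass-univariate general linear model at every
voxel (group indicator plus age, sex, scanner — total intracranial volume is
deliberately not included at this stage, matching the covariate set used
for atrophy contrasts rather than for w-scoring) and corrects for multiple
comparisons by one of three modes: uncorrected p < 0.001, Bonferroni at
family-wise 0.05, or a permutation max-T test at family-wise 0.05, which is
exact under exchangeability of group labels given the covariates.

``kruskal_wallis_profile`` compares clinical measures across clusters with
tie-corrected Kruskal–Wallis tests and unadjusted pairwise rank-sum tests;
``summarize_composition`` tabulates cluster-by-diagnosis counts with
nearest-integer row percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment
from .maps import SubjectMaps
from .wscore import _align

__all__ = [
    "StatMap",
    "CompositionTable",
    "voxelwise_contrast",
    "kruskal_wallis_profile",
    "summarize_composition",
]

CORRECTIONS = ("none_p001", "bonferroni_p05", "permutation_maxT_p05")


@dataclass
class StatMap:
    """Per-voxel group-contrast statistics with correction metadata."""

    t: np.ndarray
    p_uncorrected: np.ndarray
    significant: np.ndarray
    correction: str
    covariates_used: tuple[str, ...]
    n_group: int
    n_control: int
    df: int
    threshold: float
    constant_voxels: np.ndarray
    p_corrected: np.ndarray | None = None


def _glm_group_t(Y: np.ndarray, X: np.ndarray, group_col: int) -> tuple[np.ndarray, int]:
    """t statistic for one design column, all voxels at once."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[group_col, group_col], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[group_col] / se
    t[~np.isfinite(t)] = 0.0
    return t, df


def voxelwise_contrast(
    group_maps: SubjectMaps,
    control_maps: SubjectMaps,
    covariates: pd.DataFrame,
    correction: str = "permutation_maxT_p05",
    covariate_columns: tuple[str, ...] = ("age", "sex", "scanner"),
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    direction: str = "two-sided",
) -> StatMap:
    """Mass-univariate GLM contrast of a cluster against the control cohort.

    The design is ``[intercept, group, covariates]`` with group = 1 for
    cluster members; the reported t is for the group term, so negative t
    means lower tissue probability (atrophy) in the cluster.  The
    permutation max-T mode permutes the group labels (seeded) and uses the
    distribution of the maximum |t| across voxels as the family-wise null.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    n1, n0 = group_maps.n_subjects, control_maps.n_subjects
    if n1 < 3 or n0 < 3:
        raise ValueError("both groups need at least 3 subjects")
    if group_maps.n_voxels != control_maps.n_voxels:
        raise ValueError("groups must share the analysis mask")
    Y = np.vstack([group_maps.values, control_maps.values])
    group = np.concatenate([np.ones(n1), np.zeros(n0)])
    all_ids = list(group_maps.subject_ids) + list(control_maps.subject_ids)
    combined = SubjectMaps(
        Y, None, group_maps.voxel_size_mm, "combined", all_ids,
        group_maps.grid_shape,
    )
    cov = _align(combined, covariates)
    cols = [np.ones(len(Y)), group]
    names = ["intercept", "group"]
    for c in covariate_columns:
        if c not in cov.columns:
            raise ValueError(f"covariate table lacks column {c!r}")
        vals = cov[c]
        if vals.dtype == object:
            levels = sorted(pd.unique(vals))
            if len(levels) > 2:
                for lv in levels[1:]:
                    cols.append((vals.to_numpy() == lv).astype(float))
                    names.append(f"{c}[{lv}]")
                continue
            vals = (vals == levels[-1]).astype(float)
        cols.append(vals.to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # find the offender: a covariate collinear with group (or constant)
        bad = []
        for j in range(2, X.shape[1]):
            sub = X[:, [0, 1, j]]
            if np.linalg.matrix_rank(sub) < 3:
                bad.append(names[j])
        raise ValueError(
            "design is rank deficient; covariate(s) collinear with the "
            f"group indicator or constant: {bad or 'unidentified'}"
        )

    constant = Y.std(axis=0) == 0.0
    t, df = _glm_group_t(Y, X, group_col=1)
    t[constant] = 0.0
    p_unc = 2.0 * stats.t.sf(np.abs(t), df)

    p_corr = None
    if correction == "none_p001":
        threshold = 0.001
        significant = p_unc < threshold
    elif correction == "bonferroni_p05":
        threshold = alpha / Y.shape[1]
        significant = p_unc < threshold
    else:  # permutation max-T
        rng = np.random.default_rng(seed)
        max_t = np.empty(n_permutations)
        Xp = X.copy()
        for b in range(n_permutations):
            Xp[:, 1] = rng.permutation(group)
            tb, _ = _glm_group_t(Y, Xp, group_col=1)
            max_t[b] = np.max(np.abs(tb))
        # permutation p-value with the +1 correction (observed included)
        p_corr = (1.0 + np.sum(max_t[None, :] >= np.abs(t)[:, None], axis=1)) / (
            n_permutations + 1.0
        )
        threshold = float(np.quantile(max_t, 1.0 - alpha))
        significant = p_corr <= alpha
    return StatMap(
        t=t,
        p_uncorrected=p_unc,
        significant=significant,
        correction=correction,
        covariates_used=tuple(names[2:]),
        n_group=n1,
        n_control=n0,
        df=df,
        threshold=float(threshold),
        constant_voxels=constant,
        p_corrected=p_corr,
    )


def kruskal_wallis_profile(
    clinical: pd.DataFrame,
    assignment: ClusterAssignment | np.ndarray,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Per-measure Kruskal–Wallis test across clusters with pairwise rank-sums.

    Rows with missing values are dropped per measure.  H carries the
    standard tie correction; all-tied measures return H = 0, p = 1 with a
    warning.  Pairwise comparisons use the unadjusted Wilcoxon rank-sum
    test; the ``ns_*`` flags mark p >= 0.05.
    """
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment)
        else np.asarray(assignment, dtype=int)
    )
    if len(labels) != len(clinical):
        raise ValueError("assignment length must match clinical table rows")
    if measures is None:
        measures = [
            c for c in clinical.columns
            if c != "subject_id" and pd.api.types.is_numeric_dtype(clinical[c])
        ]
    uniq = np.unique(labels)
    rows = []
    skipped = []
    for name in measures:
        vals = clinical[name].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        groups = [vals[ok & (labels == g)] for g in uniq]
        if sum(len(g) > 0 for g in groups) < 2:
            skipped.append(name)
            warnings.warn(
                f"measure {name!r} lacks non-missing values in >= 2 "
                "clusters; skipped", stacklevel=2,
            )
            continue
        groups = [g for g in groups if len(g) > 0]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            warnings.warn(
                f"measure {name!r} is identical across all subjects; "
                "H = 0, p = 1", stacklevel=2,
            )
            H, p = 0.0, 1.0
        else:
            H, p = stats.kruskal(*groups)
        row = {"measure": name, "H": float(H), "p": float(p),
               "n_used": int(ok.sum())}
        for g1, g2 in combinations(uniq, 2):
            x = vals[ok & (labels == g1)]
            y = vals[ok & (labels == g2)]
            key = f"p_{g1}_vs_{g2}"
            if len(x) == 0 or len(y) == 0:
                row[key] = np.nan
            else:
                row[key] = float(stats.ranksums(x, y).pvalue)
            row[f"ns_{g1}_vs_{g2}"] = not (row[key] < 0.05)
        rows.append(row)
    if not rows:
        raise ValueError(
            "no clinical measure has usable (non-missing) values in at "
            "least two clusters"
        )
    return pd.DataFrame(rows)


@dataclass
class CompositionTable:
    """Cluster-by-diagnosis counts with nearest-integer row percentages."""

    counts: pd.DataFrame
    row_pct: pd.DataFrame

    def __post_init__(self) -> None:
        recomputed = (
            self.counts.div(self.counts.sum(axis=1), axis=0) * 100
        ).round().astype(int)
        if not recomputed.equals(self.row_pct):
            raise ValueError("row_pct does not recompute from counts")


def summarize_composition(
    assignment: ClusterAssignment | np.ndarray,
    diagnoses: pd.Series | np.ndarray | list,
    merge_groups: dict[str, list[str]] | None = None,
    valid_diagnoses: list[str] | None = None,
) -> CompositionTable:
    """Cluster-by-diagnosis composition with nearest-integer percentages.

    ``merge_groups`` maps a merged label to its member diagnoses (e.g.
    ``{"AOS": ["AOS-PAA", "PPAOS"]}``); unlisted diagnoses keep their own
    label.  ``valid_diagnoses`` optionally declares the allowed label set —
    any other label raises.
    """
    labels = (
        assignment.labels if isinstance(assignment, ClusterAssignment)
        else np.asarray(assignment, dtype=int)
    )
    diag = pd.Series(list(diagnoses), dtype=object)
    if len(diag) != len(labels):
        raise ValueError("diagnoses length must match assignment")
    if diag.isna().any():
        raise ValueError("missing diagnosis label(s)")
    if valid_diagnoses is not None:
        unknown = sorted(set(diag) - set(valid_diagnoses))
        if unknown:
            raise ValueError(f"unknown diagnosis label(s): {unknown}")
    if merge_groups:
        remap = {m: merged for merged, members in merge_groups.items()
                 for m in members}
        diag = diag.map(lambda d: remap.get(d, d))
    counts = pd.crosstab(pd.Series(labels, name="cluster"),
                         diag.rename("diagnosis"))
    row_pct = (counts.div(counts.sum(axis=1), axis=0) * 100).round().astype(int)
    return CompositionTable(counts=counts, row_pct=row_pct)
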