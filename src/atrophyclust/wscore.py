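"""Voxel-wise w-score normalization against a healthy reference cohort.

A w-score is a covariate-adjusted z-score: for each voxel an ordinary
least-squares regression of tissue probability on covariates (age, sex,
total intracranial volume, scanner manufacturer) is fitted on the healthy
reference cohort, and a subject's w-score is

    w = (observed - predicted) / sd(reference residuals)

so that, for a new subject drawn from the reference population, w is
approximately standard normal at every voxel.  All voxels are fitted at once
through a single least-squares solve on the ``n x p`` design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import SubjectMaps

__all__ = [
    "DesignSchema",
    "WScoreModel",
    "fit_reference",
    "compute_wscores",
    "analysis_mask",
]

LOW_VARIANCE_TOL = 1e-6


@dataclass
class DesignSchema:
    """Ordered covariate encoding used by a fitted reference model.

    ``columns`` lists design columns after the intercept.  Binary covariates
    (sex, scanner) are encoded as a single 0/1 column when the reference has
    at most two levels; more levels become one-hot columns against the first
    (sorted) level.  ``levels`` records the sorted reference levels of each
    categorical covariate so that prediction can reject unseen levels.
    """

    covariates: tuple[str, ...]
    columns: tuple[str, ...]
    levels: dict[str, tuple]

    def build(self, table: pd.DataFrame, *, strict: bool = True) -> np.ndarray:
        """Encode a covariate table into the design matrix (with intercept)."""
        missing = [c for c in self.covariates if c not in table.columns]
        if missing:
            raise ValueError(f"covariate table lacks columns: {missing}")
        cols = [np.ones(len(table))]
        names = ["intercept"]
        for cov in self.covariates:
            vals = table[cov]
            if cov in self.levels:
                lv = self.levels[cov]
                unseen = sorted(set(vals) - set(lv))
                if unseen and strict:
                    raise ValueError(
                        f"covariate {cov!r} has level(s) {unseen} unseen in "
                        f"the reference cohort (reference levels: {list(lv)})"
                    )
                if len(lv) == 2:
                    cols.append((vals.to_numpy() == lv[1]).astype(float))
                    names.append(cov)
                else:
                    for level in lv[1:]:
                        cols.append((vals.to_numpy() == level).astype(float))
                        names.append(f"{cov}[{level}]")
            else:
                if vals.isna().any():
                    raise ValueError(f"missing values in covariate {cov!r}")
                cols.append(vals.to_numpy(dtype=float))
                names.append(cov)
        X = np.column_stack(cols)
        if tuple(names) != ("intercept",) + self.columns:
            raise ValueError(
                "covariate table encoding does not match the model schema: "
                f"got {names[1:]}, expected {list(self.columns)}"
            )
        return X


@dataclass
class WScoreModel:
    """Per-voxel reference regression: coefficients and residual SD.

    ``beta`` has shape ``(1 + n_design_columns, n_voxels)``; ``resid_sd`` is
    per voxel; ``low_variance_mask`` marks voxels whose residual SD falls
    below :data:`LOW_VARIANCE_TOL` — their w-scores are defined as 0.
    """

    beta: np.ndarray
    resid_sd: np.ndarray
    schema: DesignSchema
    n_reference: int
    sd_denominator: str
    low_variance_mask: np.ndarray
    channel: str

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]


def _make_schema(
    table: pd.DataFrame, covariates: tuple[str, ...], categoricals: tuple[str, ...]
) -> DesignSchema:
    levels: dict[str, tuple] = {}
    columns: list[str] = []
    for cov in covariates:
        if cov in categoricals:
            lv = tuple(sorted(pd.unique(table[cov].dropna())))
            if len(lv) < 2:
                raise ValueError(
                    f"categorical covariate {cov!r} has fewer than 2 levels "
                    "in the reference cohort"
                )
            levels[cov] = lv
            if len(lv) == 2:
                columns.append(cov)
            else:
                columns.extend(f"{cov}[{l}]" for l in lv[1:])
        else:
            columns.append(cov)
    return DesignSchema(covariates, tuple(columns), levels)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify columns that do not increase rank when added left to right
    bad = []
    r = 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            bad.append(names[j])
        r = rj
    raise ValueError(
        f"rank-deficient design (rank {rank} < {X.shape[1]}); "
        f"collinear column(s): {bad}"
    )


def _align(maps: SubjectMaps, covariates: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" not in covariates.columns:
        raise ValueError("covariate table needs a subject_id column")
    table = covariates.set_index("subject_id")
    missing = [s for s in maps.subject_ids if s not in table.index]
    if missing:
        raise ValueError(
            f"covariate table is missing subjects: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return table.loc[maps.subject_ids].reset_index()


def fit_reference(
    controls: SubjectMaps,
    covariates: pd.DataFrame,
    covariate_columns: tuple[str, ...] = ("age", "sex", "tiv", "scanner"),
    categorical: tuple[str, ...] = ("sex", "scanner"),
    sd_denominator: str = "n-p",
) -> WScoreModel:
    """Fit the per-voxel healthy-reference regression.

    ``sd_denominator`` selects the residual-SD normalization: ``"n-p"``
    (residual degrees of freedom; default — gives w-scores unit variance for
    new reference subjects) or ``"n"``.
    """
    if sd_denominator not in ("n-p", "n"):
        raise ValueError("sd_denominator must be 'n-p' or 'n'")
    cov = _align(controls, covariates)
    schema = _make_schema(cov, covariate_columns, categorical)
    X = schema.build(cov)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} reference subjects for {p} design "
            f"columns, got {n}"
        )
    _check_rank(X, ["intercept", *schema.columns])
    Y = controls.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    denom = n - p if sd_denominator == "n-p" else n
    resid_sd = np.sqrt(np.sum(resid**2, axis=0) / denom)
    low_var = resid_sd < LOW_VARIANCE_TOL
    return WScoreModel(
        beta=beta,
        resid_sd=resid_sd,
        schema=schema,
        n_reference=n,
        sd_denominator=sd_denominator,
        low_variance_mask=low_var,
        channel=controls.channel,
    )


def compute_wscores(
    model: WScoreModel, subjects: SubjectMaps, covariates: pd.DataFrame
) -> SubjectMaps:
    """Convert subject maps to w-score maps under a fitted reference model.

    Low-variance voxels (degenerate in the reference) are set to 0 rather
    than dropped, keeping the matrix geometry identical across cohorts; the
    model's ``low_variance_mask`` reports them.
    """
    if subjects.n_voxels != model.n_voxels:
        raise ValueError(
            f"subject maps have {subjects.n_voxels} voxels but the model was "
            f"fitted on {model.n_voxels}"
        )
    cov = _align(subjects, covariates)
    X = model.schema.build(cov)
    pred = X @ model.beta
    sd = np.where(model.low_variance_mask, 1.0, model.resid_sd)
    w = (subjects.values - pred) / sd
    w[:, model.low_variance_mask] = 0.0
    if model.low_variance_mask.any():
        warnings.warn(
            f"{int(model.low_variance_mask.sum())} low-variance voxel(s) "
            "set to w = 0", stacklevel=2,
        )
    return SubjectMaps(
        w, subjects.mask, subjects.voxel_size_mm,
        f"wscore_{model.channel}", list(subjects.subject_ids),
        subjects.grid_shape,
    )


def analysis_mask(
    controls: SubjectMaps, threshold: float = 0.1
) -> np.ndarray:
    """Boolean voxel mask: mean reference tissue probability >= threshold.

    Returned on the masked-column axis (length ``n_voxels``), i.e. relative
    to the maps' existing mask.
    """
    return controls.values.mean(axis=0) >= threshold


def apply_column_mask(maps: SubjectMaps, keep: np.ndarray) -> SubjectMaps:
    """Restrict maps to a subset of masked-voxel columns."""
    keep = np.asarray(keep, dtype=bool)
    new_mask = None
    if maps.mask is not None:
        new_mask = np.zeros_like(maps.mask)
        idx = np.argwhere(maps.mask)
        kept_idx = idx[keep]
        new_mask[tuple(kept_idx.T)] = True
    return SubjectMaps(
        maps.values[:, keep], new_mask, maps.voxel_size_mm, maps.channel,
        list(maps.subject_ids), maps.grid_shape,
    )
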