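"""Core in-memory containers for voxel-map cohorts.

A :class:`SubjectMaps` holds one tissue channel (gray, white, w-score, or a
stacked concatenation) for a cohort as a dense ``subjects x masked-voxels``
matrix, together with the boolean voxel mask and grid geometry needed to
rebuild 3-D volumes.  Covariates travel separately as a plain
:class:`pandas.DataFrame` (see :mod:`atrophyclust.wscore` for the design
encoding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubjectMaps", "stack_channels"]

REQUIRED_COVARIATES = ("age", "sex", "tiv", "scanner")


@dataclass
class SubjectMaps:
    """Cohort of single-channel voxel maps restricted to an analysis mask.

    Parameters
    ----------
    values:
        ``(n_subjects, n_voxels)`` float array; column *j* corresponds to the
        *j*-th ``True`` voxel of ``mask`` in C order.  For the ``stacked``
        channel the columns are the gray-channel voxels followed by the
        white-channel voxels and ``mask`` is ``None``.
    mask:
        3-D boolean array, or ``None`` for stacked maps.
    voxel_size_mm:
        Isotropic voxel edge length in millimetres.
    channel:
        One of ``{"gray", "white", "wscore", "stacked", ...}`` — free-form
        label describing what the values are.
    subject_ids:
        Row labels, aligned with ``values``.
    """

    values: np.ndarray
    mask: np.ndarray | None
    voxel_size_mm: float
    channel: str
    subject_ids: list[str]
    grid_shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x voxels) array")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.ndim != 3:
                raise ValueError("mask must be a 3-D boolean grid")
            if self.values.shape[1] != int(self.mask.sum()):
                raise ValueError(
                    f"values has {self.values.shape[1]} columns but mask has "
                    f"{int(self.mask.sum())} voxels"
                )
            if self.grid_shape is None:
                self.grid_shape = self.mask.shape
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length must match number of rows")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_volume(self, subject: int | str, fill: float = 0.0) -> np.ndarray:
        """Scatter one subject's masked values back onto the 3-D grid."""
        if self.mask is None:
            raise ValueError("stacked maps have no single grid; unstack first")
        if isinstance(subject, str):
            subject = self.subject_ids.index(subject)
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values[subject]
        return vol

    def select(self, rows: np.ndarray) -> "SubjectMaps":
        """Row subset, preserving order of ``rows``."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SubjectMaps(
            values=self.values[rows],
            mask=self.mask,
            voxel_size_mm=self.voxel_size_mm,
            channel=self.channel,
            subject_ids=[self.subject_ids[i] for i in rows],
            grid_shape=self.grid_shape,
        )


def stack_channels(*channels: SubjectMaps) -> SubjectMaps:
    """Concatenate per-channel maps column-wise into one ``stacked`` matrix.

    All inputs must share subject ids (same order) and voxel size.  The
    stacked object keeps ``mask=None``; the per-channel geometry lives in the
    inputs, which callers should retain for writing volumes.
    """
    if not channels:
        raise ValueError("need at least one channel")
    first = channels[0]
    for ch in channels[1:]:
        if ch.subject_ids != first.subject_ids:
            raise ValueError("channels must share subject ids in order")
        if ch.voxel_size_mm != first.voxel_size_mm:
            raise ValueError("channels must share voxel size")
    return SubjectMaps(
        values=np.hstack([ch.values for ch in channels]),
        mask=None,
        voxel_size_mm=first.voxel_size_mm,
        channel="stacked",
        subject_ids=list(first.subject_ids),
        grid_shape=first.grid_shape,
    )
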