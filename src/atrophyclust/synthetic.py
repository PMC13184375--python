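"""Synthetic atrophy-cohort generator with known ground-truth subtypes.

The generator emulates the input structure of a voxel-based morphometry
subtyping study: a healthy control cohort and a patient cohort drawn from a
small number of latent anatomical subtypes.  Each subtype is a spatial
template — a set of voxels where tissue probability is reduced by
``effect_size`` control-noise standard deviations.  Covariate confounds
(age slope, sex offset, TIV scaling, scanner offset) act linearly on every
voxel, and voxel-wise Gaussian noise is added on top.  Values are clipped to
[0, 1] so the maps remain valid tissue probabilities.

Everything is driven by a single integer seed: the same
:class:`CohortConfig` always yields bit-identical cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .maps import SubjectMaps

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_clinical_table",
    "smooth_map",
    "CLINICAL_MEASURES",
]

#: default linear covariate effects on the tissue-probability scale
DEFAULT_COVARIATE_EFFECTS = {
    "age_slope": -0.002,   # probability units per year of age
    "sex_offset": 0.01,    # male-vs-female offset
    "tiv_slope": 0.02,     # per standard deviation of TIV
    "scanner_offset": 0.01,  # second-manufacturer offset
}

#: clinical measures with (lower bound, upper bound or None, healthy-ish mean, SD)
CLINICAL_MEASURES = {
    "moca": (0.0, 30.0, 22.0, 4.0),
    "mds_updrs_iii": (0.0, None, 15.0, 10.0),
    "psp_rating_scale": (0.0, 100.0, 15.0, 10.0),
    "asrs_total": (0.0, 52.0, 8.0, 6.0),
    "fab": (0.0, 18.0, 13.0, 3.0),
    "bnt": (0.0, 15.0, 11.0, 3.0),
    "letter_fluency_sum": (0.0, None, 12.0, 7.0),
    "wab_praxis": (0.0, 60.0, 54.0, 6.0),
    "wab_aq": (0.0, 100.0, 88.0, 9.0),
    "wab_repetition": (0.0, 10.0, 9.0, 0.8),
    "wab_animal_fluency": (0.0, None, 11.0, 4.0),
    "ppt_word_word": (0.0, 52.0, 47.0, 4.0),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the template atrophy depth in units of the control
    voxel noise SD; ``covariate_effects`` maps the four confound names to
    their linear coefficients on the tissue-probability scale.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 2.0
    n_controls: int = 100
    n_patients_per_subtype: tuple[int, ...] = (40, 40, 40)
    n_subtypes: int = 3
    effect_size: float = 2.0
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = 0.05
    seed: int = 0
    baseline: dict = field(
        default_factory=lambda: {"gray": 0.55, "white": 0.45}
    )

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if int(np.prod(self.grid_shape)) < 64:
            raise ValueError("grid must contain at least 64 voxels")
        if not 2 <= self.n_subtypes <= 4:
            raise ValueError("n_subtypes must be in 2..4")
        if len(self.n_patients_per_subtype) != self.n_subtypes:
            raise ValueError(
                "n_patients_per_subtype length must equal n_subtypes"
            )
        if self.n_controls <= 0 or any(
            n <= 0 for n in self.n_patients_per_subtype
        ):
            raise ValueError("every cohort group needs at least one subject")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``subtype_label`` holds one integer in ``1..n_subtypes`` per patient,
    aligned with the patient maps; ``template_masks`` holds one boolean grid
    per subtype marking the voxels whose generating mean is reduced.
    """

    subtype_label: np.ndarray
    template_masks: list[np.ndarray]
    generating_covariates: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        self.subtype_label = np.asarray(self.subtype_label, dtype=int)
        k = len(self.template_masks)
        if not np.all((self.subtype_label >= 1) & (self.subtype_label <= k)):
            raise ValueError("labels must lie in 1..n_subtypes")
        for m in self.template_masks:
            if not np.any(m):
                raise ValueError("every template mask must be non-empty")


def _subtype_templates(grid_shape: tuple[int, int, int], k: int) -> list[np.ndarray]:
    """Disjoint cuboid templates: split the first axis into k slabs and keep
    the central half of each slab (so templates sit away from grid edges)."""
    masks = []
    nx = grid_shape[0]
    edges = np.linspace(0, nx, k + 1).astype(int)
    for i in range(k):
        lo, hi = edges[i], edges[i + 1]
        pad = max(1, (hi - lo) // 4)
        m = np.zeros(grid_shape, dtype=bool)
        m[lo + pad // 2 : hi - pad // 2,
          grid_shape[1] // 4 : 3 * grid_shape[1] // 4,
          grid_shape[2] // 4 : 3 * grid_shape[2] // 4] = True
        if not m.any():  # degenerate tiny grids: keep at least one voxel
            m[(lo + hi) // 2, grid_shape[1] // 2, grid_shape[2] // 2] = True
        masks.append(m)
    return masks


def _draw_covariates(rng: np.random.Generator, n: int, prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i:04d}" for i in range(n)],
            "age": rng.uniform(55.0, 80.0, size=n),
            "sex": rng.integers(0, 2, size=n),
            "tiv": rng.normal(1400.0, 120.0, size=n),
            "scanner": rng.integers(0, 2, size=n),
        }
    )


def _covariate_signal(
    cov: pd.DataFrame, effects: dict, n_voxels: int
) -> np.ndarray:
    """Per-subject scalar confound term, broadcast over voxels.

    Age and TIV are centred on their generating means (67.5 y, 1400 ml /
    120 ml SD) so the baseline stays the cohort-typical value.
    """
    term = (
        effects.get("age_slope", 0.0) * (cov["age"].to_numpy() - 67.5)
        + effects.get("sex_offset", 0.0) * cov["sex"].to_numpy()
        + effects.get("tiv_slope", 0.0) * (cov["tiv"].to_numpy() - 1400.0) / 120.0
        + effects.get("scanner_offset", 0.0) * cov["scanner"].to_numpy()
    )
    return np.broadcast_to(term[:, None], (len(term), n_voxels)).copy()


def generate_cohort(
    config: CohortConfig,
) -> tuple[
    dict[str, SubjectMaps], pd.DataFrame,
    dict[str, SubjectMaps], pd.DataFrame,
    SyntheticTruth,
]:
    """Generate control and patient cohorts with known subtype structure.

    Returns
    -------
    controls, control_covariates, patients, patient_covariates, truth
        ``controls`` and ``patients`` are ``{"gray": SubjectMaps, "white":
        SubjectMaps}`` dictionaries; gray and white channels are generated
        independently (independent noise draws) but share the same subtype
        templates and covariate coefficients.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    k = config.n_subtypes
    templates = _subtype_templates(config.grid_shape, k)
    n_pat = int(sum(config.n_patients_per_subtype))

    cov_ctrl = _draw_covariates(rng, config.n_controls, "ctrl")
    cov_pat = _draw_covariates(rng, n_pat, "pat")

    labels = np.concatenate(
        [np.full(n, i + 1) for i, n in enumerate(config.n_patients_per_subtype)]
    ).astype(int)

    n_vox = int(np.prod(config.grid_shape))
    flat_templates = [m.ravel() for m in templates]

    controls: dict[str, SubjectMaps] = {}
    patients: dict[str, SubjectMaps] = {}
    full_mask = np.ones(config.grid_shape, dtype=bool)
    for channel, base in config.baseline.items():
        sig_c = _covariate_signal(cov_ctrl, config.covariate_effects, n_vox)
        sig_p = _covariate_signal(cov_pat, config.covariate_effects, n_vox)
        vals_c = base + sig_c + rng.normal(0.0, config.noise_sd, (config.n_controls, n_vox))
        vals_p = base + sig_p + rng.normal(0.0, config.noise_sd, (n_pat, n_vox))
        depth = config.effect_size * config.noise_sd
        for i in range(n_pat):
            vals_p[i, flat_templates[labels[i] - 1]] -= depth
        np.clip(vals_c, 0.0, 1.0, out=vals_c)
        np.clip(vals_p, 0.0, 1.0, out=vals_p)
        controls[channel] = SubjectMaps(
            vals_c, full_mask, config.voxel_size_mm, channel,
            list(cov_ctrl["subject_id"]),
        )
        patients[channel] = SubjectMaps(
            vals_p, full_mask, config.voxel_size_mm, channel,
            list(cov_pat["subject_id"]),
        )

    truth = SyntheticTruth(
        subtype_label=labels,
        template_masks=templates,
        generating_covariates=pd.concat([cov_ctrl, cov_pat], ignore_index=True),
        seed=config.seed,
    )
    return controls, cov_ctrl, patients, cov_pat, truth


def generate_clinical_table(
    truth: SyntheticTruth,
    config: CohortConfig,
    subtype_shifts: dict[str, tuple[float, ...]] | None = None,
    missing_fraction: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Clinical-measures table with per-subtype mean shifts.

    ``subtype_shifts`` maps a measure name to one shift per subtype, in units
    of that measure's SD; unlisted measures get no shift.  With all shifts
    zero the measures carry no group structure at all.  ``missing_fraction``
    of cells are blanked at random (uniformly across measures).
    """
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValueError("missing_fraction must be in [0, 1]")
    subtype_shifts = subtype_shifts or {}
    for name in subtype_shifts:
        if name not in CLINICAL_MEASURES:
            raise KeyError(f"unknown clinical measure: {name!r}")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = len(truth.subtype_label)
    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"pat{i:04d}" for i in range(n)], dtype=object)
    }
    for name, (lo, hi, mean, sd) in CLINICAL_MEASURES.items():
        vals = rng.normal(mean, sd, size=n)
        shifts = subtype_shifts.get(name)
        if shifts is not None:
            if len(shifts) != len(truth.template_masks):
                raise ValueError(
                    f"need one shift per subtype for measure {name!r}"
                )
            vals = vals + sd * np.asarray(shifts)[truth.subtype_label - 1]
        vals = np.clip(vals, lo, hi if hi is not None else np.inf)
        if missing_fraction > 0:
            drop = rng.random(n) < missing_fraction
            vals = vals.astype(float)
            vals[drop] = np.nan
        data[name] = vals
    return pd.DataFrame(data)


def smooth_map(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float
) -> np.ndarray:
    """Isotropic Gaussian smoothing of one 3-D volume.

    The kernel width is given as full width at half maximum in millimetres
    and converted to a sigma of ``fwhm / (2 * sqrt(2 * ln 2))`` in voxel
    units.  Edge handling replicates the boundary voxel, so a constant
    volume is left exactly unchanged and interior-supported signal keeps its
    total sum.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if fwhm_mm < voxel_size_mm:
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below the voxel size {voxel_size_mm} mm; "
            "smoothing anyway", stacklevel=2,
        )
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_size_mm
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=float), sigma=sigma_vox, mode="nearest"
    )


def smooth_subject_maps(maps: SubjectMaps, fwhm_mm: float) -> SubjectMaps:
    """Smooth every subject volume of a single-channel :class:`SubjectMaps`."""
    if maps.mask is None:
        raise ValueError("cannot smooth stacked maps; smooth each channel")
    out = np.empty_like(maps.values)
    for i in range(maps.n_subjects):
        vol = maps.to_volume(i)
        out[i] = smooth_map(vol, fwhm_mm, maps.voxel_size_mm)[maps.mask]
    return SubjectMaps(
        out, maps.mask, maps.voxel_size_mm, maps.channel,
        list(maps.subject_ids), maps.grid_shape,
    )
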