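"""End-to-end orchestration of the subtyping analysis.

Stage order: (optional smoothing) -> per-channel w-scoring against the
healthy reference -> stacking of gray + white w-score maps -> KMO
sampling-adequacy check -> PCA with the 1%-variance retention rule ->
consensus clustering ensemble for each candidate K -> Calinski–Harabasz
comparison and (optional) leave-one-out stability -> cluster
characterization (composition, clinical profiles, voxel-wise atrophy
contrasts) -> optional robustness re-run on the raw, non-w-scored maps.

A single root seed drives every stochastic stage; stage-level sub-seeds are
derived deterministically from it, so a run is reproducible from its
persisted config alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterAssignment, ConsensusParams, consensus_ensemble
from .dimred import kmo_voxel_subsample, reduce_maps
from .evaluation import (
    StabilityReport,
    adjusted_rand,
    loo_stability,
    rand_index,
    select_k,
)
from .group_stats import (
    CompositionTable,
    kruskal_wallis_profile,
    summarize_composition,
    voxelwise_contrast,
)
from .maps import SubjectMaps, stack_channels
from .synthetic import (
    CohortConfig,
    generate_clinical_table,
    generate_cohort,
    smooth_subject_maps,
)
from .wscore import analysis_mask, apply_column_mask, compute_wscores, fit_reference

logger = logging.getLogger("atrophyclust")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "raw_map_check"]

#: default per-subtype clinical shifts (units of measure SD), so that the
#: Kruskal–Wallis stage of a synthetic run has detectable structure:
#: each subtype is impaired on its own signature measure.
DEFAULT_CLINICAL_SHIFT_MEASURES = ("moca", "mds_updrs_iii", "bnt", "asrs_total")


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the root seed."""
    h = np.random.SeedSequence(
        root, spawn_key=tuple(stage.encode())
    ).generate_state(1)[0]
    return int(h % (2**31))


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (exactly one input mode)."""

    seed: int
    synthetic: CohortConfig | None = None
    input_dir: str | None = None
    covariates_csv: str | None = None
    clinical_csv: str | None = None
    smooth_fwhm_mm: float = 8.0
    smooth_before_wscore: bool = True
    sd_denominator: str = "n-p"
    mask_threshold: float = 0.1
    min_var_frac: float = 0.01
    max_components: int | None = None
    kmo_voxels: int = 500
    subsample_frac: float = 0.8
    ensemble_reps: int = 10
    algorithms: tuple[str, ...] = ("hc", "diana")
    linkage: str = "average"
    k_candidates: tuple[int, ...] = (2, 3, 4)
    report_k: int | None = None
    correction: str = "bonferroni_p05"
    n_permutations: int = 1000
    run_loo: bool = False
    run_contrasts: bool = True
    raw_check: bool = False
    output_dir: str | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        modes = [self.synthetic is not None, self.input_dir is not None]
        if sum(modes) != 1:
            raise ValueError(
                "exactly one input mode required: synthetic config or "
                "NIfTI input directory"
            )
        if self.synthetic is not None:
            self.synthetic.validate()

    def ensemble_params(self, stage: str = "ensemble") -> ConsensusParams:
        return ConsensusParams(
            subsample_frac=self.subsample_frac,
            reps=self.ensemble_reps,
            algorithms=tuple(self.algorithms),
            linkage=self.linkage,
            seed=_stage_seed(self.seed, stage),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            for key in ("grid_shape", "n_patients_per_subtype"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = CohortConfig(**syn)
        for key in ("algorithms", "k_candidates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = asdict(self.synthetic)
            for key in ("grid_shape", "n_patients_per_subtype"):
                d["synthetic"][key] = list(d["synthetic"][key])
        d["algorithms"] = list(self.algorithms)
        d["k_candidates"] = list(self.k_candidates)
        return d


@dataclass
class RunReport:
    """Everything a run computed, plus provenance to recompute it."""

    kmo: float
    explained_fraction: list[float]
    n_components: int
    per_k: dict
    report_k: int
    ch_maximal_k: int
    final_labels: list[int]
    stability: dict | None
    composition_counts: dict | None
    composition_pct: dict | None
    clinical_tests: list[dict] | None
    stat_map_paths: dict
    raw_vs_wscored_rand: float | None
    adjusted_rand_vs_truth: float | None
    provenance: dict
    intermediates: dict = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "intermediates"}
        text = json.dumps(payload, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text


def _log_stage(stage: str, t0: float, **info) -> None:
    logger.info(
        "stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0,
        " ".join(f"{k}={v}" for k, v in info.items()),
    )


def _load_inputs(config: RunConfig):
    """Returns (controls, cov_ctrl, patients, cov_pat, clinical, diagnoses,
    truth) with controls/patients as {channel: SubjectMaps}."""
    if config.synthetic is not None:
        controls, cov_c, patients, cov_p, truth = generate_cohort(
            config.synthetic
        )
        k = config.synthetic.n_subtypes
        shifts = {
            m: tuple(-1.5 if j == i else 0.0 for j in range(k))
            for i, m in enumerate(DEFAULT_CLINICAL_SHIFT_MEASURES[:k])
        }
        clinical = generate_clinical_table(
            truth, config.synthetic, subtype_shifts=shifts,
            seed=_stage_seed(config.seed, "clinical"),
        )
        clinical["subject_id"] = cov_p["subject_id"].to_numpy()
        diagnoses = pd.Series(
            [f"subtype{l}" for l in truth.subtype_label], dtype=object
        )
        return controls, cov_c, patients, cov_p, clinical, diagnoses, truth
    from .io import read_covariates, read_subject_maps

    cov = read_covariates(config.covariates_csv)
    cov_c = cov[cov["group"] == "control"].reset_index(drop=True)
    cov_p = cov[cov["group"] == "patient"].reset_index(drop=True)
    controls = {}
    patients = {}
    for channel in ("gray", "white"):
        controls[channel] = read_subject_maps(
            config.input_dir, channel, list(cov_c["subject_id"])
        )
        patients[channel] = read_subject_maps(
            config.input_dir, channel, list(cov_p["subject_id"])
        )
    clinical = (
        read_covariates(config.clinical_csv) if config.clinical_csv else None
    )
    diagnoses = (
        cov_p["diagnosis"] if "diagnosis" in cov_p.columns else None
    )
    return controls, cov_c, patients, cov_p, clinical, diagnoses, None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and return a :class:`RunReport`.

    ``config.report_k`` selects the partition used for characterization;
    when ``None`` the CH-maximal K is used and the choice is logged, so a
    substantively motivated override is always explicit in the provenance.
    """
    config.validate()
    t0 = time.perf_counter()
    controls, cov_c, patients, cov_p, clinical, diagnoses, truth = (
        _load_inputs(config)
    )
    if not patients or next(iter(patients.values())).n_subjects == 0:
        raise ValueError("empty patient cohort")
    _log_stage("load", t0,
               n_controls=next(iter(controls.values())).n_subjects,
               n_patients=next(iter(patients.values())).n_subjects)

    def _smooth(cohort):
        if config.smooth_fwhm_mm and config.smooth_fwhm_mm > 0:
            return {
                ch: smooth_subject_maps(m, config.smooth_fwhm_mm)
                for ch, m in cohort.items()
            }
        return cohort

    if config.smooth_before_wscore:
        controls = _smooth(controls)
        patients = _smooth(patients)

    # per-channel analysis mask from the reference cohort
    t0 = time.perf_counter()
    wsc_patients = {}
    raw_patients = {}
    masked_controls = {}
    for ch in controls:
        keep = analysis_mask(controls[ch], config.mask_threshold)
        ctrl = apply_column_mask(controls[ch], keep)
        pat = apply_column_mask(patients[ch], keep)
        model = fit_reference(
            ctrl, cov_c, sd_denominator=config.sd_denominator
        )
        wsc = compute_wscores(model, pat, cov_p)
        if not config.smooth_before_wscore:
            wsc = smooth_subject_maps(wsc, config.smooth_fwhm_mm)
            pat = smooth_subject_maps(pat, config.smooth_fwhm_mm)
            ctrl = smooth_subject_maps(ctrl, config.smooth_fwhm_mm)
        wsc_patients[ch] = wsc
        raw_patients[ch] = pat
        masked_controls[ch] = ctrl
    stacked_w = stack_channels(*wsc_patients.values())
    stacked_raw = stack_channels(*raw_patients.values())
    _log_stage("wscore", t0, voxels=stacked_w.n_voxels)

    t0 = time.perf_counter()
    kmo = kmo_voxel_subsample(
        stacked_w, config.kmo_voxels, seed=_stage_seed(config.seed, "kmo")
    )
    scores = reduce_maps(
        stacked_w, config.min_var_frac, config.max_components
    )
    _log_stage("pca", t0, kmo=round(kmo, 4), m=scores.m)

    t0 = time.perf_counter()
    ktable = select_k(scores, tuple(config.k_candidates),
                      config.ensemble_params())
    ch_max_k = int(ktable.loc[ktable["ch_maximal"], "K"].iloc[0])
    report_k = config.report_k if config.report_k is not None else ch_max_k
    if report_k != ch_max_k:
        logger.info(
            "report_k=%d overrides CH-maximal K=%d", report_k, ch_max_k
        )
    krow = ktable[ktable["K"] == report_k]
    if krow.empty:
        raise ValueError(
            f"report_k={report_k} is not among candidates "
            f"{list(config.k_candidates)}"
        )
    final: ClusterAssignment = krow["assignment"].iloc[0]
    _log_stage("select_k", t0,
               ch={int(r.K): round(r.ch_index, 3) for r in ktable.itertuples()})

    stability = None
    if config.run_loo:
        t0 = time.perf_counter()
        rep = loo_stability(
            scores, report_k, config.ensemble_params("loo"),
            full_result=krow["result"].iloc[0],
        )
        stability = rep.summary | {"n_folds": len(rep.per_fold),
                                   "failures": rep.failures}
        _log_stage("loo", t0, folds=len(rep.per_fold))

    composition_counts = composition_pct = None
    if diagnoses is not None:
        comp = summarize_composition(final, diagnoses)
        composition_counts = {
            str(c): comp.counts.loc[c].to_dict() for c in comp.counts.index
        }
        composition_pct = {
            str(c): comp.row_pct.loc[c].to_dict() for c in comp.row_pct.index
        }

    clinical_tests = None
    if clinical is not None:
        try:
            clinical_tests = kruskal_wallis_profile(clinical, final).to_dict(
                "records"
            )
        except ValueError as exc:
            logger.warning("clinical profile skipped: %s", exc)

    stat_map_paths: dict = {}
    if config.run_contrasts:
        t0 = time.perf_counter()
        from .io import write_stat_map

        for k_lab in range(1, report_k + 1):
            members = final.labels == k_lab
            if members.sum() < 3:
                logger.warning(
                    "cluster %d has %d members; contrast skipped",
                    k_lab, int(members.sum()),
                )
                continue
            for ch in raw_patients:
                stat = voxelwise_contrast(
                    raw_patients[ch].select(members),
                    masked_controls[ch],
                    pd.concat([cov_p, cov_c], ignore_index=True),
                    correction=config.correction,
                    n_permutations=config.n_permutations,
                    seed=_stage_seed(config.seed, f"perm_{k_lab}_{ch}"),
                )
                key = f"cluster{k_lab}_{ch}"
                if config.output_dir:
                    paths = write_stat_map(
                        stat, raw_patients[ch].mask,
                        raw_patients[ch].voxel_size_mm,
                        Path(config.output_dir) / "statmaps" / key,
                    )
                    stat_map_paths[key] = {k: str(v) for k, v in paths.items()}
                else:
                    stat_map_paths[key] = {
                        "n_significant": int(stat.significant.sum())
                    }
        _log_stage("contrasts", t0, maps=len(stat_map_paths))

    ari_truth = None
    if truth is not None and report_k == len(truth.template_masks):
        ari_truth = adjusted_rand(final.labels, truth.subtype_label)

    report = RunReport(
        kmo=float(kmo),
        explained_fraction=[float(f) for f in scores.explained_fraction],
        n_components=scores.m,
        per_k={
            int(r.K): {
                "ch_index": float(r.ch_index),
                "labels": [int(x) for x in r.assignment.labels],
            }
            for r in ktable.itertuples()
        },
        report_k=int(report_k),
        ch_maximal_k=ch_max_k,
        final_labels=[int(x) for x in final.labels],
        stability=stability,
        composition_counts=composition_counts,
        composition_pct=composition_pct,
        clinical_tests=clinical_tests,
        stat_map_paths=stat_map_paths,
        raw_vs_wscored_rand=None,
        adjusted_rand_vs_truth=(
            float(ari_truth) if ari_truth is not None else None
        ),
        provenance={
            "config": config.to_dict(),
            "package_version": __version__,
        },
        intermediates={
            "scores": scores,
            "stacked_wscores": stacked_w,
            "stacked_raw": stacked_raw,
            "cov_patients": cov_p,
            "final": final,
            "truth": truth,
            "ktable": ktable,
        },
    )
    if config.raw_check:
        report.raw_vs_wscored_rand = raw_map_check(config, report)
    if config.output_dir:
        report.to_json(Path(config.output_dir) / "run_report.json")
    return report


def raw_map_check(config: RunConfig, wscored_result: RunReport) -> float:
    """Robustness re-run on the raw (non-w-scored) maps.

    Repeats PCA + consensus ensemble on the masked, optionally smoothed,
    raw tissue maps at the same K and seed and returns the Rand index
    between the raw-map and w-scored partitions.  Agreement indicates that
    the partition reflects anatomy rather than the covariate adjustment.
    """
    stacked_raw: SubjectMaps = wscored_result.intermediates["stacked_raw"]
    final: ClusterAssignment = wscored_result.intermediates["final"]
    scores_raw = reduce_maps(
        stacked_raw, config.min_var_frac, config.max_components
    )
    res = consensus_ensemble(
        scores_raw, wscored_result.report_k, config.ensemble_params()
    )
    wscored_result.intermediates["raw_final"] = res.final
    return float(rand_index(res.final.labels, final.labels))
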