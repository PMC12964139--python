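"""End-to-end driver: cohort -> wave fields -> phase pipeline -> inversion
-> skeleton statistics -> tract-ROI statistics -> report.

The statistics/atlas grid and the wave/inversion grid are decoupled:
wave simulation and inversion run on a block-downsampled property grid
(factor ``wave_downsample``), and recovered maps are upsampled back to
the atlas grid for skeleton and ROI analyses.  This mirrors the
resolution gap between elastography acquisition and standard-space
voxelwise analysis in human studies, and keeps the nonlinear inversion
affordable on one CPU.

Every output file name embeds a short hash of the configuration, and a
rerun with the same configuration and master seed reproduces the report
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nifti
from .forward import DisplacementField, default_actuations, simulate_multi_excitation
from .inversion import InversionConfig, derived_maps, invert_iso, invert_ti
from .material import NITIVolume, PhysicsConstants
from .phantom import (
    Cohort,
    CohortConfig,
    PhantomAtlas,
    TRACT_NAMES,
    build_atlas,
    sample_cohort,
)
from .preproc import displacement_from_phase, encode_phase, oss_snr
from .roistats import added_value_logistic, bonferroni, group_ttest, roi_skeleton_means
from .skeleton import (
    make_skeleton,
    overlap_classes,
    percent_significant,
    project_to_skeleton,
    voxelwise_group_test,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "STAGES"]

STAGES = ("cohort", "wave", "invert", "skeleton", "roi", "report")

MRE_PARAMS = ["mu2", "mu1", "mu_iso", "phi", "zeta"]
DTI_PARAMS = ["fa", "md", "rd", "mk"]


@dataclass
class PipelineConfig:
    """Full study configuration; every stage validates its slice."""

    atlas_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing_mm: float = 2.0
    n_young: int = 20
    n_old: int = 18
    master_seed: int = 0
    # physics / acquisition
    density: float = 1000.0
    frequency: float = 50.0
    bulk_modulus: float = 1.0e7
    amplitude_m: float = 10e-6
    sensitivity: float = 1.0e5  # rad per meter (micron-scale motion -> ~1 rad)
    phase_noise_sd: float = 0.0  # radians per phase image
    wave_downsample: int = 2
    # inversion
    inversion_max_iterations: int = 10
    inversion_reg_weight: float = 1e-5
    oss_threshold: float = 3.0
    # statistics
    alpha: float = 0.05
    n_perm: int = 500
    fa_threshold: float = 0.2
    bonferroni_k: int = 8
    logistic_bases: Tuple[str, ...] = ("fa", "md")
    logistic_added: Tuple[str, ...] = ("mu2", "mu1", "mu_iso", "phi", "zeta")
    write_volumes: bool = True

    def __post_init__(self) -> None:
        self.atlas_shape = tuple(int(s) for s in self.atlas_shape)
        self.logistic_bases = tuple(self.logistic_bases)
        self.logistic_added = tuple(self.logistic_added)

    def validate(self) -> None:
        if any(s % self.wave_downsample for s in self.atlas_shape):
            raise ValueError(
                f"atlas shape {self.atlas_shape} must be divisible by wave_downsample={self.wave_downsample}"
            )
        self.cohort_config()  # raises on bad group sizes etc.
        self.inversion_config()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for p in self.logistic_bases:
            if p not in DTI_PARAMS:
                raise ValueError(f"unknown logistic base covariate {p!r}")
        for p in self.logistic_added:
            if p not in MRE_PARAMS:
                raise ValueError(f"unknown logistic added covariate {p!r}")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_young=self.n_young, n_old=self.n_old, seed=self.master_seed)

    def constants(self) -> PhysicsConstants:
        return PhysicsConstants(self.density, self.frequency, self.bulk_modulus)

    def inversion_config(self) -> InversionConfig:
        return InversionConfig(
            max_iterations=self.inversion_max_iterations,
            reg_weight=self.inversion_reg_weight,
            oss_threshold=self.oss_threshold,
            seed=self.master_seed,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:10]


@dataclass
class RunReport:
    """Tables and provenance emitted by the pipeline."""

    qc: pd.DataFrame
    table1: pd.DataFrame
    percent_significant: pd.DataFrame
    overlap: pd.DataFrame
    regression: pd.DataFrame
    stage_status: Dict[str, str]
    provenance: Dict[str, str]

    def sections(self) -> Dict[str, pd.DataFrame]:
        return {
            "qc": self.qc,
            "table1": self.table1,
            "percent_significant": self.percent_significant,
            "overlap": self.overlap,
            "regression": self.regression,
        }


def _block_downsample(vol: np.ndarray, f: int) -> np.ndarray:
    s = vol.shape
    return vol.reshape(s[0] // f, f, s[1] // f, f, s[2] // f, f).mean(axis=(1, 3, 5))


def _downsample_niti(vol: NITIVolume, f: int) -> NITIVolume:
    if f == 1:
        return vol
    fib = np.stack([_block_downsample(vol.fibers[..., c], f) for c in range(3)], axis=-1)
    n = np.linalg.norm(fib, axis=-1, keepdims=True)
    fib = np.where(n > 1e-9, fib / np.where(n > 0, n, 1.0), [0.0, 0.0, 1.0])
    return NITIVolume(
        mu2_storage=_block_downsample(vol.mu2_storage, f),
        mu2_loss=_block_downsample(vol.mu2_loss, f),
        phi=_block_downsample(vol.phi, f),
        zeta=_block_downsample(vol.zeta, f),
        fibers=fib,
    )


def _upsample(vol: np.ndarray, f: int) -> np.ndarray:
    out = vol
    for ax in range(3):
        out = np.repeat(out, f, axis=ax)
    return out


def _noise_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir: str | Path, through: str = "report") -> RunReport:
    """Run all stages up to ``through``; outputs are written as stages finish."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}, expected one of {STAGES}")
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    (out / f"{h}_config.json").write_text(config.to_json())
    status: Dict[str, str] = {}
    last = STAGES.index(through)
    t_start = time.time()

    def done(stage: str) -> bool:
        return STAGES.index(stage) >= last

    # ---- stage: cohort ---------------------------------------------------
    atlas = build_atlas(config.atlas_shape, config.spacing_mm)
    cohort = sample_cohort(atlas, config.cohort_config())
    manifest = cohort.manifest()
    manifest.to_csv(out / f"{h}_cohort_manifest.csv", index=False)
    if config.write_volumes:
        nifti.write_volume(atlas.labels, out / f"{h}_atlas_labels.nii.gz", config.spacing_mm)
        for s in cohort.subjects:
            for p in ("mu2", "phi", "zeta", "fa"):
                nifti.write_volume(
                    s.maps[p], out / f"{h}_sub{s.subject_id:04d}_{p}_truth.nii.gz", config.spacing_mm
                )
    status["cohort"] = "ok"
    if done("cohort"):
        return _empty_report(status, config, h)

    # ---- stage: wave (forward + phase pipeline + QC) ---------------------
    consts = config.constants()
    f = config.wave_downsample
    wave_spacing = config.spacing_mm * f * 1e-3
    wave_node_shape = tuple(s // f + 1 for s in config.atlas_shape)
    acts = default_actuations(wave_node_shape, config.amplitude_m, config.frequency)
    noise_sd_disp = config.phase_noise_sd / (2.0 * config.sensitivity)
    loss_ratio = cohort.config.loss_ratio

    measured: Dict[int, Dict[str, DisplacementField]] = {}
    fibers_ds: Dict[int, np.ndarray] = {}
    qc_rows: List[dict] = []
    for si, s in enumerate(cohort.subjects):
        vol = _downsample_niti(s.to_niti(atlas, loss_ratio), f)
        fibers_ds[s.subject_id] = vol.fibers
        fields = simulate_multi_excitation(vol, consts, acts.values(), spacing_m=wave_spacing)
        measured[s.subject_id] = {}
        for ei, (exc, fld) in enumerate(sorted(fields.items())):
            series = encode_phase(
                fld,
                sensitivity=config.sensitivity,
                noise_sd=config.phase_noise_sd,
                seed=_noise_seed(config.master_seed, 1, si, ei),
            )
            rec = displacement_from_phase(series)
            qc = oss_snr(rec, noise_sd_disp, threshold=config.oss_threshold)
            measured[s.subject_id][exc] = rec
            qc_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "excitation": exc,
                    "oss_snr": qc.oss_snr,
                    "passed": qc.passed,
                }
            )
            if config.write_volumes:
                nifti.write_field(
                    rec.data, out / f"{h}_sub{s.subject_id:04d}_{exc}", config.spacing_mm * f
                )
    qc_table = pd.DataFrame(qc_rows)
    qc_table.to_csv(out / f"{h}_qc.csv", index=False)
    status["wave"] = "ok"
    if done("wave"):
        return _empty_report(status, config, h, qc=qc_table)

    # ---- stage: invert ---------------------------------------------------
    inv_cfg = config.inversion_config()
    recovered: Dict[int, Dict[str, np.ndarray]] = {}
    conv_rows = []
    for s in cohort.subjects:
        flds = measured[s.subject_id]
        maps = invert_ti(
            [flds["AP"], flds["LR"]], fibers_ds[s.subject_id], consts, inv_cfg
        )
        mu_iso = invert_iso(flds["AP"], consts, inv_cfg)
        dmaps = derived_maps(maps, mu_iso)
        rec = {
            "mu2": _upsample(dmaps.mu2, f) / 1000.0,  # kPa at the reporting boundary
            "mu1": _upsample(dmaps.mu1, f) / 1000.0,
            "mu_iso": _upsample(mu_iso, f) / 1000.0,
            "phi": _upsample(maps.phi, f),
            "zeta": _upsample(maps.zeta, f),
        }
        recovered[s.subject_id] = rec
        conv_rows.append(
            {
                "subject_id": s.subject_id,
                "status": maps.status,
                "iterations": len(maps.misfit_history) - 1,
                "final_misfit": maps.data_misfit,
            }
        )
        if config.write_volumes:
            for p, v in rec.items():
                nifti.write_volume(v, out / f"{h}_sub{s.subject_id:04d}_{p}_rec.nii.gz", config.spacing_mm)
    pd.DataFrame(conv_rows).to_csv(out / f"{h}_inversion_convergence.csv", index=False)
    status["invert"] = "ok"
    if done("invert"):
        return _empty_report(status, config, h, qc=qc_table)

    # ---- stage: skeleton statistics --------------------------------------
    mean_fa = cohort.mean_map("fa")
    skeleton = make_skeleton(mean_fa, config.fa_threshold)
    if config.write_volumes:
        nifti.write_volume(skeleton.mask.astype(np.int8), out / f"{h}_skeleton.nii.gz", config.spacing_mm)
    labels = list(cohort.labels)

    def subject_param_map(s, p):
        return recovered[s.subject_id][p] if p in MRE_PARAMS else s.maps[p]

    projected: Dict[str, np.ndarray] = {}
    for p in MRE_PARAMS + DTI_PARAMS:
        projected[p] = np.stack(
            [project_to_skeleton(subject_param_map(s, p), s.maps["fa"], skeleton) for s in cohort.subjects]
        )
    stat_maps = {
        p: voxelwise_group_test(
            projected[p], labels, alpha=config.alpha, n_perm=config.n_perm,
            seed=_noise_seed(config.master_seed, 2, i),
        )
        for i, p in enumerate(MRE_PARAMS + DTI_PARAMS)
    }
    pct_rows = []
    for p, sm_ in stat_maps.items():
        pct_rows.append(
            {
                "parameter": p,
                "pct_young_gt_old": percent_significant(sm_, "greater"),
                "pct_old_gt_young": percent_significant(sm_, "less"),
                "n_skeleton": skeleton.n_voxels,
            }
        )
    pct_table = pd.DataFrame(pct_rows)
    pct_table.to_csv(out / f"{h}_percent_significant.csv", index=False)

    ov_rows = []
    for pm in MRE_PARAMS:
        for pd_ in DTI_PARAMS:
            ov = overlap_classes(
                stat_maps[pm].significant("greater"), stat_maps[pd_].significant("greater")
            )
            ov_rows.append({"mre": pm, "dti": pd_, **ov.counts})
    ov_table = pd.DataFrame(ov_rows)
    ov_table.to_csv(out / f"{h}_overlap.csv", index=False)
    status["skeleton"] = "ok"
    if done("skeleton"):
        return _empty_report(status, config, h, qc=qc_table,
                             percent_significant=pct_table, overlap=ov_table)

    # ---- stage: ROI statistics -------------------------------------------
    tract_values: Dict[str, Dict[str, np.ndarray]] = {}
    for p in MRE_PARAMS + DTI_PARAMS:
        per_tract: Dict[str, List[float]] = {t: [] for t in TRACT_NAMES}
        for s in cohort.subjects:
            means, _ = roi_skeleton_means(subject_param_map(s, p), atlas, skeleton)
            for t in TRACT_NAMES:
                per_tract[t].append(means[t])
        tract_values[p] = {t: np.asarray(v) for t, v in per_tract.items()}

    young = np.asarray(labels) == "young"
    t1_rows = []
    for p in MRE_PARAMS + DTI_PARAMS:
        pvals = []
        for t in TRACT_NAMES:
            vy = tract_values[p][t][young]
            vo = tract_values[p][t][~young]
            res = group_ttest(vy, vo)
            pvals.append(res.p)
            t1_rows.append(
                {
                    "tract": t,
                    "parameter": p,
                    "mean_young": vy.mean(),
                    "sd_young": vy.std(ddof=1),
                    "min_young": vy.min(),
                    "max_young": vy.max(),
                    "mean_old": vo.mean(),
                    "sd_old": vo.std(ddof=1),
                    "min_old": vo.min(),
                    "max_old": vo.max(),
                    "t": res.t,
                    "p": res.p,
                }
            )
        flags, thr = bonferroni(pvals, config.alpha, config.bonferroni_k)
        for row, fl in zip(t1_rows[-len(TRACT_NAMES):], flags):
            row["significant_bonferroni"] = bool(fl)
            row["threshold"] = thr
    t1_table = pd.DataFrame(t1_rows)
    t1_table.to_csv(out / f"{h}_table1_style.csv", index=False)

    reg_rows = []
    for base_p in config.logistic_bases:
        for added_p in config.logistic_added:
            for t in TRACT_NAMES:
                res = added_value_logistic(
                    tract_values[base_p][t], tract_values[added_p][t], labels,
                    base_name=base_p, added_name=added_p,
                )
                reg_rows.append(
                    {
                        "tract": t,
                        "base": base_p,
                        "added": added_p,
                        "beta": res.beta,
                        "p": res.p,
                        "converged": res.converged,
                        "separation": res.separation,
                        "collinear": res.collinear,
                    }
                )
    reg_table = pd.DataFrame(reg_rows)
    reg_table.to_csv(out / f"{h}_regression.csv", index=False)
    status["roi"] = "ok"

    # ---- stage: report ----------------------------------------------------
    provenance = {
        "config_hash": h,
        "master_seed": str(config.master_seed),
        "elapsed_s": f"{time.time() - t_start:.1f}",
    }
    report = RunReport(
        qc=qc_table,
        table1=t1_table,
        percent_significant=pct_table,
        overlap=ov_table,
        regression=reg_table,
        stage_status=status,
        provenance=provenance,
    )
    summary = {
        "provenance": provenance,
        "stages": status,
        "qc_all_passed": bool(qc_table["passed"].all()),
        "n_subjects": len(cohort.subjects),
    }
    (out / f"{h}_report.json").write_text(json.dumps(summary, indent=1))
    status["report"] = "ok"
    return report


def _empty_report(status, config, h, qc=None, percent_significant=None, overlap=None) -> RunReport:
    empty = pd.DataFrame()
    return RunReport(
        qc=qc if qc is not None else empty,
        table1=empty,
        percent_significant=percent_significant if percent_significant is not None else empty,
        overlap=overlap if overlap is not None else empty,
        regression=empty,
        stage_status=status,
        provenance={"config_hash": h, "master_seed": str(config.master_seed)},
    )
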