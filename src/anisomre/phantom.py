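"""Digital white-matter phantom and synthetic subject cohorts.

A deterministic box phantom stands in for the registered standard-space
brain: an ellipsoidal "brain" with a gray-matter shell, background white
matter, and eight geometrically simple tract ROIs (bars, columns and
sheets) named after the major tracts they emulate — corpus callosum
body (CCB), forceps major/minor (FMAJ/FMIN), corona radiata (CR),
corticospinal tract (CST), anterior/posterior thalamic radiations
(ATR/PTR), and superior longitudinal fasciculus (SLF).  Every tract
voxel carries a unit fiber vector along the tract tangent.

Subjects are drawn as in a two-group cross-sectional study: for each
tract and parameter one tract-level value is sampled from the group's
Normal(mean, SD) — the between-subject variability — and voxel noise
models within-tract heterogeneity.  Default group means and SDs for the
mechanical parameters (mu2 stiffness in kPa, shear anisotropy phi,
tensile anisotropy zeta) encode the published young-adult (n=20) versus
older-adult (n=18) tract statistics; DTI-like map defaults (FA, MD, RD,
MK) are plausible assumed values (lower FA/MK, higher MD/RD in the
older group), configurable and not literature-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .material import NITIVolume, storage_from_stiffness

__all__ = [
    "TRACT_NAMES",
    "LABELS",
    "PhantomAtlas",
    "CohortConfig",
    "SubjectSample",
    "Cohort",
    "build_atlas",
    "sample_subject",
    "sample_cohort",
    "TABLE1_PARAMS",
]

TRACT_NAMES = ["CCB", "FMAJ", "FMIN", "CR", "CST", "ATR", "PTR", "SLF"]
LABELS = {"OUTSIDE": 0, "GM": 1, "WM": 2}
LABELS.update({name: 3 + i for i, name in enumerate(TRACT_NAMES)})

MECH_PARAMS = ["mu2", "phi", "zeta"]
DTI_PARAMS = ["fa", "md", "rd", "mk"]
ALL_PARAMS = MECH_PARAMS + DTI_PARAMS

# Group means/SDs per tract: {tract: {param: (mean_y, sd_y, mean_o, sd_o)}}.
# mu2 is the composite shear stiffness in kPa; phi and zeta dimensionless.
TABLE1_PARAMS: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {
    "CCB": {"mu2": (2.47, 0.29, 2.47, 0.35), "phi": (0.25, 0.10, 0.18, 0.09), "zeta": (1.11, 0.16, 0.83, 0.13)},
    "FMAJ": {"mu2": (2.74, 0.20, 2.62, 0.19), "phi": (0.01, 0.09, -0.07, 0.12), "zeta": (1.10, 0.19, 0.96, 0.13)},
    "FMIN": {"mu2": (2.94, 0.23, 2.61, 0.23), "phi": (0.05, 0.05, -0.06, 0.07), "zeta": (0.88, 0.20, 0.53, 0.20)},
    "CR": {"mu2": (2.71, 0.12, 2.61, 0.17), "phi": (0.19, 0.03, 0.10, 0.05), "zeta": (1.05, 0.13, 0.76, 0.12)},
    "CST": {"mu2": (2.79, 0.22, 2.73, 0.22), "phi": (0.35, 0.07, 0.25, 0.06), "zeta": (1.13, 0.13, 0.88, 0.14)},
    "ATR": {"mu2": (3.00, 0.15, 2.78, 0.21), "phi": (0.09, 0.03, 0.04, 0.04), "zeta": (1.01, 0.16, 0.75, 0.13)},
    "PTR": {"mu2": (2.86, 0.17, 2.73, 0.20), "phi": (-0.04, 0.10, -0.07, 0.07), "zeta": (1.17, 0.19, 1.01, 0.09)},
    "SLF": {"mu2": (2.72, 0.13, 2.67, 0.15), "phi": (0.10, 0.03, 0.02, 0.04), "zeta": (1.02, 0.14, 0.79, 0.09)},
}

# Assumed DTI-like defaults, identical across tracts (young vs old):
# lower FA and MK, higher MD and RD in the older group.  MD/RD in um^2/ms.
_DTI_DEFAULTS: Dict[str, Tuple[float, float, float, float]] = {
    "fa": (0.55, 0.04, 0.50, 0.04),
    "md": (0.75, 0.04, 0.80, 0.05),
    "rd": (0.55, 0.04, 0.62, 0.05),
    "mk": (1.05, 0.08, 0.95, 0.08),
}

# Background tissue values (not drawn per subject, shared constants).
# Background WM FA is kept below the 0.2 skeleton threshold so the
# mean-FA skeleton follows the tract cores.
BACKGROUND = {
    "WM": {"mu2": 2.5, "phi": 0.05, "zeta": 0.60, "fa": 0.15, "md": 0.85, "rd": 0.70, "mk": 0.85},
    "GM": {"mu2": 2.2, "phi": 0.0, "zeta": 0.0, "fa": 0.10, "md": 0.90, "rd": 0.80, "mk": 0.70},
    "OUTSIDE": {"mu2": 2.0, "phi": 0.0, "zeta": 0.0, "fa": 0.02, "md": 1.5, "rd": 1.3, "mk": 0.1},
}

# physical clipping bounds per parameter (draws and voxel values)
_CLIP = {
    "mu2": (0.5, 12.0),
    "phi": (-0.65, 2.0),
    "zeta": (-0.65, 4.0),
    "fa": (0.0, 1.0),
    "md": (0.05, 3.5),
    "rd": (0.05, 3.5),
    "mk": (0.0, 3.0),
}

_DEFAULT_VOXEL_NOISE = {
    "mu2": 0.08, "phi": 0.02, "zeta": 0.04,
    "fa": 0.02, "md": 0.02, "rd": 0.02, "mk": 0.04,
}

# fractional extents of each tract: list of (xlo, xhi, ylo, yhi, zlo, zhi)
# boxes plus the fiber tangent.  x is left-right, y anterior-posterior,
# z inferior-superior.
_S35 = np.array([0.0, 0.8, 0.6])
_TRACT_GEOMETRY: Dict[str, Tuple[List[Tuple[float, ...]], np.ndarray]] = {
    "CCB": ([(0.36, 0.64, 0.42, 0.58, 0.62, 0.74)], np.array([1.0, 0.0, 0.0])),
    "FMAJ": ([(0.30, 0.70, 0.80, 0.92, 0.44, 0.56)], np.array([1.0, 0.0, 0.0])),
    "FMIN": ([(0.30, 0.70, 0.08, 0.20, 0.44, 0.56)], np.array([1.0, 0.0, 0.0])),
    "CR": ([(0.24, 0.34, 0.30, 0.70, 0.55, 0.80), (0.66, 0.76, 0.30, 0.70, 0.55, 0.80)], np.array([0.0, 0.0, 1.0])),
    "CST": ([(0.36, 0.46, 0.44, 0.56, 0.14, 0.54), (0.54, 0.64, 0.44, 0.56, 0.14, 0.54)], np.array([0.0, 0.0, 1.0])),
    "ATR": ([(0.36, 0.46, 0.20, 0.42, 0.46, 0.62), (0.54, 0.64, 0.20, 0.42, 0.46, 0.62)], _S35 / np.linalg.norm(_S35)),
    "PTR": ([(0.36, 0.46, 0.58, 0.80, 0.46, 0.62), (0.54, 0.64, 0.58, 0.80, 0.46, 0.62)], np.array([0.0, 0.8, -0.6]) / np.linalg.norm(_S35)),
    "SLF": ([(0.10, 0.22, 0.30, 0.70, 0.52, 0.66), (0.78, 0.90, 0.30, 0.70, 0.52, 0.66)], np.array([0.0, 1.0, 0.0])),
}


@dataclass
class PhantomAtlas:
    """Tract label volume plus voxelwise fiber directions on a regular grid."""

    labels: np.ndarray
    fibers: np.ndarray
    spacing_mm: float

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def tract_mask(self, tract: str) -> np.ndarray:
        return self.labels == LABELS[tract]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def tract_voxel_counts(self) -> Dict[str, int]:
        return {t: int(np.sum(self.labels == LABELS[t])) for t in TRACT_NAMES}


def build_atlas(shape: Tuple[int, int, int] = (32, 32, 32), spacing_mm: float = 2.0) -> PhantomAtlas:
    """Deterministic phantom atlas with 8 mutually exclusive tracts.

    Tract extents are specified as fractions of the grid, so the same
    geometry is produced at any resolution; each axis must be >= 24
    voxels for every tract to retain at least ~50 voxels.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 24 for s in shape):
        raise ValueError(f"grid shape {shape} too small: need >= 24 voxels per axis to fit 8 tracts")
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)

    # ellipsoidal brain with a gray-matter shell
    fx, fy, fz = np.meshgrid(
        (np.arange(nx) + 0.5) / nx, (np.arange(ny) + 0.5) / ny, (np.arange(nz) + 0.5) / nz,
        indexing="ij",
    )
    r2 = ((fx - 0.5) / 0.48) ** 2 + ((fy - 0.5) / 0.48) ** 2 + ((fz - 0.5) / 0.48) ** 2
    labels[r2 <= 1.0] = LABELS["GM"]
    labels[r2 <= 0.82**2] = LABELS["WM"]

    fibers = np.zeros(shape + (3,))
    fibers[..., 2] = 1.0  # arbitrary default axis outside tracts

    for tract in TRACT_NAMES:
        boxes, tangent = _TRACT_GEOMETRY[tract]
        for (xlo, xhi, ylo, yhi, zlo, zhi) in boxes:
            sl = (
                slice(round(xlo * nx), round(xhi * nx)),
                slice(round(ylo * ny), round(yhi * ny)),
                slice(round(zlo * nz), round(zhi * nz)),
            )
            if np.any(labels[sl] >= 3):  # pragma: no cover - geometry guard
                raise RuntimeError(f"tract {tract} overlaps a previously placed tract")
            labels[sl] = LABELS[tract]
            fibers[sl] = tangent / np.linalg.norm(tangent)
    return PhantomAtlas(labels=labels, fibers=fibers, spacing_mm=float(spacing_mm))


@dataclass
class CohortConfig:
    """Study-design configuration for the synthetic two-group cohort."""

    n_young: int = 20
    n_old: int = 18
    tract_params: Dict[str, Dict[str, Tuple[float, float, float, float]]] = field(default_factory=dict)
    voxel_noise_sd: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_VOXEL_NOISE))
    loss_ratio: float = 0.30  # G''/G' used to realize complex moduli from stiffness
    seed: int = 0

    def __post_init__(self) -> None:
        merged: Dict[str, Dict[str, Tuple[float, float, float, float]]] = {}
        for tract in TRACT_NAMES:
            merged[tract] = dict(TABLE1_PARAMS[tract])
            merged[tract].update({p: _DTI_DEFAULTS[p] for p in DTI_PARAMS})
            merged[tract].update(self.tract_params.get(tract, {}))
        self.tract_params = merged
        self.validate()

    def validate(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError(f"group sizes must be >= 2, got n_young={self.n_young}, n_old={self.n_old}")
        if not 0 <= self.loss_ratio:
            raise ValueError("loss_ratio must be >= 0")
        for tract, params in self.tract_params.items():
            for p, (my, sy, mo, so) in params.items():
                if sy < 0 or so < 0:
                    raise ValueError(f"negative SD for {tract}/{p}")
                if p == "fa" and not (0.2 < my < 1 and 0.2 < mo < 1):
                    raise ValueError(f"tract FA means must lie in (0.2, 1), got {tract}: {my}, {mo}")
        for p, sd in self.voxel_noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative voxel noise SD for {p}")

    def group_mean_sd(self, tract: str, param: str, group: str) -> Tuple[float, float]:
        my, sy, mo, so = self.tract_params[tract][param]
        if group == "young":
            return my, sy
        if group == "old":
            return mo, so
        raise ValueError(f"unknown group label {group!r}: expected 'young' or 'old'")


@dataclass
class SubjectSample:
    """One synthetic subject: ground-truth parameter and DTI-like maps."""

    subject_id: int
    group: str
    maps: Dict[str, np.ndarray]
    draws: Dict[str, Dict[str, float]]
    n_clipped: int
    seed: int

    def to_niti(self, atlas: PhantomAtlas, loss_ratio: float) -> NITIVolume:
        """Ground-truth NITI parameter volume for the forward solver."""
        gstorage = storage_from_stiffness(self.maps["mu2"] * 1000.0, loss_ratio)
        return NITIVolume(
            mu2_storage=gstorage,
            mu2_loss=loss_ratio * gstorage,
            phi=self.maps["phi"],
            zeta=self.maps["zeta"],
            fibers=atlas.fibers,
        )


@dataclass
class Cohort:
    atlas: PhantomAtlas
    config: CohortConfig
    subjects: List[SubjectSample]

    def group(self, label: str) -> List[SubjectSample]:
        return [s for s in self.subjects if s.group == label]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def mean_map(self, param: str) -> np.ndarray:
        return np.mean([s.maps[param] for s in self.subjects], axis=0)

    def manifest(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group, "seed": s.seed, "n_clipped": s.n_clipped}
            for tract, params in s.draws.items():
                for p, v in params.items():
                    row[f"{tract}_{p}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _subject_rng(master_seed: int, subject_id: int) -> np.random.Generator:
    # counter-based substream: stable under cohort reordering/resizing
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_id,)))


def sample_subject(
    atlas: PhantomAtlas, config: CohortConfig, group: str, subject_id: int
) -> SubjectSample:
    """Draw one subject: tract-level Normal draws plus voxel noise."""
    if group not in ("young", "old"):
        raise ValueError(f"unknown group label {group!r}: expected 'young' or 'old'")
    rng = _subject_rng(config.seed, subject_id)
    maps = {p: np.zeros(atlas.shape) for p in ALL_PARAMS}
    n_clipped = 0

    for region in ("OUTSIDE", "GM", "WM"):
        mask = atlas.labels == LABELS[region]
        for p in ALL_PARAMS:
            maps[p][mask] = BACKGROUND[region][p]

    draws: Dict[str, Dict[str, float]] = {}
    for tract in TRACT_NAMES:
        mask = atlas.tract_mask(tract)
        draws[tract] = {}
        for p in ALL_PARAMS:
            mean, sd = config.group_mean_sd(tract, p, group)
            value = float(rng.normal(mean, sd))
            lo, hi = _CLIP[p]
            clipped = min(max(value, lo), hi)
            n_clipped += int(clipped != value)
            draws[tract][p] = clipped
            maps[p][mask] = clipped

    # zero-mean voxel noise everywhere inside the brain, then re-clip
    brain = atlas.brain_mask
    for p in ALL_PARAMS:
        sd = config.voxel_noise_sd.get(p, 0.0)
        if sd > 0:
            noise = rng.normal(0.0, sd, size=atlas.shape)
            maps[p][brain] += noise[brain]
        lo, hi = _CLIP[p]
        np.clip(maps[p], lo, hi, out=maps[p])

    return SubjectSample(
        subject_id=subject_id, group=group, maps=maps, draws=draws,
        n_clipped=n_clipped, seed=config.seed,
    )


def sample_cohort(atlas: PhantomAtlas, config: CohortConfig) -> Cohort:
    """Sample the full two-group cohort with per-subject substreams."""
    config.validate()
    subjects = [sample_subject(atlas, config, "young", i) for i in range(config.n_young)]
    # fixed id offset keeps older-adult substreams stable if n_young changes
    subjects += [sample_subject(atlas, config, "old", 1000 + i) for i in range(config.n_old)]
    return Cohort(atlas=atlas, config=config, subjects=subjects)
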