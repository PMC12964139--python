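"""Skeleton-based voxelwise group statistics (TBSS-style).

The white-matter skeleton is the medial sheet of the mean-FA mask
(FA > 0.2): a voxel belongs to the skeleton when the distance-to-edge
transform is a local maximum along the local sheet normal.  Subject
maps are projected onto the skeleton by searching along that normal for
each subject's maximal-FA voxel, mimicking the projection step that
compensates residual misalignment.  Group inference is a voxelwise
pooled-variance two-sample t statistic with p-values from the
group-label permutation null, evaluated for both contrast directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "SkeletonMask",
    "StatMap",
    "OverlapMap",
    "make_skeleton",
    "project_to_skeleton",
    "voxelwise_group_test",
    "percent_significant",
    "overlap_classes",
]


@dataclass
class SkeletonMask:
    mask: np.ndarray  # boolean volume
    mean_fa: np.ndarray
    normals: np.ndarray  # unit sheet-normal per voxel, (grid, 3)
    threshold: float = 0.2

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class StatMap:
    """Voxelwise permutation test result on the skeleton."""

    t_stat: np.ndarray  # (n_voxels,) observed pooled t (A - B)
    p_greater: np.ndarray  # P(A > B)
    p_less: np.ndarray  # P(B > A)
    p_two: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    contrast: Tuple[str, str]  # (A, B) group labels
    n_zero_variance: int = 0
    dropped_voxels: int = 0

    def significant(self, direction: str = "greater") -> np.ndarray:
        p = {"greater": self.p_greater, "less": self.p_less, "two": self.p_two}[direction]
        return p <= self.alpha


@dataclass
class OverlapMap:
    classes: np.ndarray  # (n_voxels,) int codes
    counts: Dict[str, int] = field(default_factory=dict)

    CODES = {"neither": 0, "mre_only": 1, "dti_only": 2, "both": 3}


def _sheet_normals(volume: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Unit normals from the gradient of the smoothed volume."""
    sm = ndimage.gaussian_filter(volume.astype(float), sigma)
    g = np.stack(np.gradient(sm), axis=-1)
    n = np.linalg.norm(g, axis=-1, keepdims=True)
    out = np.where(n > 1e-12, g / np.where(n > 0, n, 1.0), 0.0)
    # degenerate gradient (ridge center, flat regions): fall back to z
    flat = n[..., 0] <= 1e-12
    out[flat] = np.array([0.0, 0.0, 1.0])
    return out


def _sample(volume: np.ndarray, points: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(
        volume.astype(float), points.T, order=order, mode="nearest"
    )


def make_skeleton(mean_fa: np.ndarray, threshold: float = 0.2) -> SkeletonMask:
    """Medial-sheet skeleton of the thresholded mean-FA volume.

    Deterministic: distance transform of the FA > threshold mask,
    normals from its smoothed gradient, and a local-maximum test of the
    distance transform at +/- 1 voxel along the normal.
    """
    fa = np.asarray(mean_fa, dtype=float)
    if fa.min() < 0 or fa.max() > 1:
        raise ValueError("FA must lie in [0, 1]")
    mask = fa > threshold
    skeleton = np.zeros_like(mask)
    normals = np.zeros(fa.shape + (3,))
    normals[..., 2] = 1.0
    if not mask.any():
        return SkeletonMask(mask=skeleton, mean_fa=fa, normals=normals, threshold=threshold)
    dist = ndimage.distance_transform_edt(mask)
    normals = _sheet_normals(dist)
    idx = np.argwhere(mask).astype(float)
    nvec = normals[mask]
    d0 = dist[mask]
    d_plus = _sample(dist, idx + nvec)
    d_minus = _sample(dist, idx - nvec)
    keep = (d0 >= d_plus - 1e-9) & (d0 >= d_minus - 1e-9)
    skeleton[tuple(np.argwhere(mask)[keep].T)] = True
    return SkeletonMask(mask=skeleton, mean_fa=fa, normals=normals, threshold=threshold)


def project_to_skeleton(
    subject_map: np.ndarray,
    subject_fa: np.ndarray,
    skeleton: SkeletonMask,
    search_radius: float = 2.0,
) -> np.ndarray:
    """Project one subject's map onto the skeleton.

    For each skeleton voxel, searches +/- ``search_radius`` voxels along
    the local sheet normal for the subject's maximal-FA position and
    samples the subject map there (nearest voxel).  Voxels whose whole
    search window falls below the FA threshold are returned as NaN
    (missing) so downstream tests can drop them listwise.
    """
    if subject_map.shape != skeleton.mask.shape:
        raise ValueError(
            f"subject map shape {subject_map.shape} != skeleton grid {skeleton.mask.shape}"
        )
    idx = skeleton.indices.astype(float)
    nvec = skeleton.normals[skeleton.mask]
    # search outward from the skeleton voxel so FA ties resolve to the
    # nearest position (identical subject => direct sampling)
    half = np.arange(0.5, search_radius + 0.25, 0.5)
    offsets = np.concatenate([[0.0], np.stack([half, -half], axis=1).ravel()])
    fa_samples = np.empty((len(offsets), len(idx)))
    for k, t in enumerate(offsets):
        fa_samples[k] = _sample(subject_fa, idx + t * nvec, order=0)
    best = np.argmax(fa_samples, axis=0)
    best_fa = fa_samples[best, np.arange(len(idx))]
    pts = idx + offsets[best][:, None] * nvec
    vals = _sample(subject_map, pts, order=0)
    vals[best_fa <= skeleton.threshold] = np.nan
    return vals


def _pooled_t(
    x: np.ndarray, in_a: np.ndarray, in_b: np.ndarray, valid: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance t over voxels with listwise NaN handling.

    x: (n_subj, n_vox) with NaN for missing; in_a/in_b boolean (n_perm?, n_subj).
    Returns (t, zero_variance_mask) broadcast over leading axes of in_a.
    """
    xz = np.where(valid, np.nan_to_num(x), 0.0)
    x2z = np.where(valid, np.nan_to_num(x * x), 0.0)
    na = in_a.astype(float) @ valid.astype(float)  # (..., n_vox)
    nb = in_b.astype(float) @ valid.astype(float)
    sa = in_a.astype(float) @ xz
    sb = in_b.astype(float) @ xz
    qa = in_a.astype(float) @ x2z
    qb = in_b.astype(float) @ x2z
    with np.errstate(divide="ignore", invalid="ignore"):
        ma = sa / na
        mb = sb / nb
        ssa = qa - na * ma**2
        ssb = qb - nb * mb**2
        df = np.maximum(na + nb - 2, 1.0)
        sp2 = (ssa + ssb) / df
        zero = ~(sp2 > 1e-300)  # catches zero variance and empty groups (NaN)
        denom = np.sqrt(np.where(zero, 1.0, sp2) * (1 / na + 1 / nb))
        t = (ma - mb) / denom
    return np.where(zero, 0.0, np.nan_to_num(t)), zero


def voxelwise_group_test(
    values: np.ndarray,
    labels: Sequence[str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_coverage: float = 0.8,
) -> StatMap:
    """Permutation two-sample t-test per skeleton voxel.

    ``values`` is (n_subjects, n_voxels), NaN marking missing projected
    values; ``labels`` the group label per subject (exactly two distinct
    labels, first-seen label is contrast side A).  The same ``n_perm``
    label shuffles are shared across voxels.  Voxels with fewer than
    ``min_coverage`` of subjects present are dropped (p = NaN).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    a_mask = labels == groups[0]
    b_mask = labels == groups[1]
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("need >= 2 subjects per group")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} < 100 gives a very coarse permutation null")

    n_subj, n_vox = values.shape
    valid = np.isfinite(values)
    coverage = valid.mean(axis=0)
    dropped = coverage < min_coverage

    t_obs, zero_var = _pooled_t(values, a_mask[None], b_mask[None], valid)
    t_obs = t_obs[0]
    zero_var = zero_var[0]

    rng = np.random.default_rng(seed)
    perm_a = np.zeros((n_perm, n_subj), dtype=bool)
    na = int(a_mask.sum())
    for i in range(n_perm):
        perm = rng.permutation(n_subj)
        perm_a[i, perm[:na]] = True
    t_perm, _ = _pooled_t(values, perm_a, ~perm_a, valid)

    # one-sided and two-sided permutation p-values with add-one correction
    p_greater = (1 + np.sum(t_perm >= t_obs[None], axis=0)) / (n_perm + 1)
    p_less = (1 + np.sum(t_perm <= t_obs[None], axis=0)) / (n_perm + 1)
    p_two = (1 + np.sum(np.abs(t_perm) >= np.abs(t_obs)[None], axis=0)) / (n_perm + 1)
    for p in (p_greater, p_less, p_two):
        p[zero_var] = 1.0  # flat voxels carry no evidence
        p[dropped] = np.nan
    return StatMap(
        t_stat=t_obs,
        p_greater=p_greater,
        p_less=p_less,
        p_two=p_two,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        contrast=(str(groups[0]), str(groups[1])),
        n_zero_variance=int(zero_var.sum()),
        dropped_voxels=int(dropped.sum()),
    )


def percent_significant(stat: StatMap, direction: str = "greater") -> float:
    """100 x significant / evaluated skeleton voxels for one contrast direction."""
    p = {"greater": stat.p_greater, "less": stat.p_less, "two": stat.p_two}[direction]
    ok = np.isfinite(p)
    if not ok.any():
        return 0.0
    return 100.0 * float(np.sum(p[ok] <= stat.alpha)) / float(ok.sum())


def overlap_classes(sig_mre: np.ndarray, sig_dti: np.ndarray) -> OverlapMap:
    """Classify each skeleton voxel by MRE/DTI significance membership."""
    sig_mre = np.asarray(sig_mre, dtype=bool)
    sig_dti = np.asarray(sig_dti, dtype=bool)
    if sig_mre.shape != sig_dti.shape:
        raise ValueError("significance masks must share the skeleton shape")
    classes = np.zeros(sig_mre.shape, dtype=np.int8)
    classes[sig_mre & ~sig_dti] = OverlapMap.CODES["mre_only"]
    classes[~sig_mre & sig_dti] = OverlapMap.CODES["dti_only"]
    classes[sig_mre & sig_dti] = OverlapMap.CODES["both"]
    counts = {name: int(np.sum(classes == code)) for name, code in OverlapMap.CODES.items()}
    return OverlapMap(classes=classes, counts=counts)
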