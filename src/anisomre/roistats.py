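"""Tract-ROI group statistics and added-value logistic regression.

ROI analysis restricts each parameter map to (tract mask AND skeleton),
averages per subject, and compares groups by pooled-variance Student
t-tests with Bonferroni correction across the eight tracts.  The
added-value analysis asks whether an elastography covariate carries
group information beyond a diffusion covariate: a logistic model
P(old) = logit^{-1}(b0 + b1 * base + b2 * added) fit per tract, with a
Wald test of the added term.  Covariates are standardized internally
for a stable fit; coefficients are reported on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .phantom import TRACT_NAMES, LABELS, PhantomAtlas
from .skeleton import SkeletonMask

__all__ = [
    "GroupSummary",
    "TestResult",
    "AddedTermResult",
    "roi_skeleton_means",
    "group_ttest",
    "ttest_from_summary",
    "bonferroni",
    "added_value_logistic",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one tract/parameter/group cell."""

    mean: float
    sd: float
    n: int
    minimum: float = np.nan
    maximum: float = np.nan

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if np.isfinite(self.minimum) and np.isfinite(self.maximum):
            if not (self.minimum <= self.mean <= self.maximum):
                raise ValueError("min <= mean <= max violated")


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    df: int

    def significant(self, threshold: float) -> bool:
        return self.p < threshold


@dataclass
class AddedTermResult:
    """Wald test of the added covariate in the two-covariate logistic model."""

    beta: float  # raw-scale coefficient of the added covariate
    p: float  # Wald p-value (NaN when not converged / separated)
    base_name: str
    added_name: str
    converged: bool
    separation: bool
    collinear: bool


def roi_skeleton_means(
    volume: np.ndarray,
    atlas: PhantomAtlas,
    skeleton: SkeletonMask,
) -> Tuple[Dict[str, float], Dict[str, int]]:
    """Mean of ``volume`` over (tract AND skeleton) per tract.

    Returns (means, voxel counts); tracts whose intersection with the
    skeleton is empty get NaN and count 0.
    """
    if volume.shape != atlas.shape or skeleton.mask.shape != atlas.shape:
        raise ValueError("volume, atlas and skeleton must share one grid")
    means: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for tract in TRACT_NAMES:
        sel = (atlas.labels == LABELS[tract]) & skeleton.mask
        counts[tract] = int(sel.sum())
        means[tract] = float(volume[sel].mean()) if counts[tract] else float("nan")
    return means, counts


def group_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample Student t-test, two-tailed."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(t=float(t), p=float(p), df=len(a) + len(b) - 2)


def ttest_from_summary(summary_a: GroupSummary, summary_b: GroupSummary) -> TestResult:
    """Pooled t-test from (mean, SD, n) — identical to group_ttest on raw data."""
    t, p = stats.ttest_ind_from_stats(
        summary_a.mean, summary_a.sd, summary_a.n,
        summary_b.mean, summary_b.sd, summary_b.n,
        equal_var=True,
    )
    return TestResult(t=float(t), p=float(p), df=summary_a.n + summary_b.n - 2)


def bonferroni(
    p_values: Sequence[float], alpha: float = 0.05, k: int = 8
) -> Tuple[np.ndarray, float]:
    """Strict Bonferroni: flags p < alpha/k; returns (flags, per-test threshold)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    threshold = alpha / k
    return np.asarray(p_values, dtype=float) < threshold, threshold


def added_value_logistic(
    base: Sequence[float],
    added: Sequence[float],
    labels: Sequence[str],
    base_name: str = "base",
    added_name: str = "added",
    positive_label: str = "old",
    test: str = "lrt",
) -> AddedTermResult:
    """Does the added covariate separate groups beyond the base covariate?

    Maximum-likelihood logistic fit of group on (base, added).  The
    added term's p-value comes from the likelihood-ratio test against
    the base-only model by default (well calibrated at these sample
    sizes); ``test="wald"`` selects the Wald test instead.  Degenerate
    geometries are flagged rather than reported as spurious estimates:
    exact collinearity of the two covariates, and (quasi-)separation
    where the likelihood is unbounded and coefficients diverge.
    """
    if test not in ("lrt", "wald"):
        raise ValueError("test must be 'lrt' or 'wald'")
    base = np.asarray(base, dtype=float)
    added = np.asarray(added, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(float)
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    if len(base) != len(added) or len(base) != len(y):
        raise ValueError("base, added and labels must have one value per subject")

    def z(v):
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    zb, za = z(base), z(added)
    X = sm.add_constant(np.column_stack([zb, za]))
    if np.linalg.matrix_rank(X) < 3 or abs(np.corrcoef(zb, za)[0, 1]) > 1 - 1e-10:
        return AddedTermResult(np.nan, np.nan, base_name, added_name,
                               converged=False, separation=False, collinear=True)
    # the added covariate alone separating the groups exactly makes the
    # likelihood unbounded regardless of the optimizer's stopping point
    if added[y == 1].min() > added[y == 0].max() or added[y == 1].max() < added[y == 0].min():
        return AddedTermResult(np.nan, np.nan, base_name, added_name,
                               converged=False, separation=True, collinear=False)
    separation = False
    converged = False
    beta_std = np.nan
    p = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
            beta_std = float(fit.params[2])
            if test == "wald":
                p = float(fit.pvalues[2])
            else:
                base_fit = sm.Logit(y, X[:, :2]).fit(disp=0, maxiter=200)
                lr = 2.0 * (fit.llf - base_fit.llf)
                p = float(stats.chi2.sf(max(lr, 0.0), 1))
        # diverging coefficients on standardized covariates indicate
        # (quasi-)separation: the reported p would be meaningless there
        if np.abs(fit.params).max() > 50 or not np.isfinite(fit.bse).all():
            separation = True
    except Exception:
        separation = True
    if separation or not converged:
        return AddedTermResult(np.nan, np.nan, base_name, added_name,
                               converged=converged, separation=separation, collinear=False)
    sd_added = added.std(ddof=1)
    beta_raw = beta_std / sd_added if sd_added > 0 else np.nan
    return AddedTermResult(beta=beta_raw, p=p, base_name=base_name, added_name=added_name,
                           converged=True, separation=False, collinear=False)
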