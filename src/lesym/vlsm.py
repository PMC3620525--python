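"""Voxel-based lesion-symptom mapping (VLSM).

At every eligible voxel, patients are split into lesioned and intact groups
and their (covariate-residualised) cognitive scores are compared with a
two-sample t-test.  Multiple testing is handled by Benjamini–Hochberg FDR
over the eligible voxels, and the surviving voxels are grouped into 3D
connected components.

Sign convention: ``t = (mean_intact - mean_lesioned) / pooled SE``, so a
positive t means that patients lesioned at the voxel perform worse.  The
default p-value is one-sided in that deficit direction; two-sided p-values
are available via ``alternative="two-sided"``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure
from sklearn.base import BaseEstimator

from .cohort import AnalysisMask, LesionCohort, analysis_mask, prevalence_map
from .grid import VoxelGrid

__all__ = [
    "TMap",
    "FDRResult",
    "ClusterLabels",
    "InsufficientCoverageError",
    "voxelwise_t",
    "bh_fdr",
    "label_clusters",
    "LesionSymptomMapper",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


class InsufficientCoverageError(RuntimeError):
    """No voxel reaches the minimum lesioned-patient count for this class."""


@dataclass
class TMap:
    """Per-voxel t statistics on the analysis mask.

    Arrays are full-grid; voxels outside the mask (or dropped for zero
    pooled variance) are NaN in ``t``/``p`` and marked False in ``valid``.
    ``df = n_lesioned + n_intact - 2`` at each voxel (all patients enter
    every voxel's test, so df is constant unless patients are missing).
    """

    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    valid: np.ndarray
    mask: AnalysisMask
    lesion_class: str
    alternative: str
    sign_convention: str = "intact_minus_lesioned"
    domain: str | None = None
    n_dropped_zero_variance: int = 0

    @property
    def grid(self) -> VoxelGrid:
        return self.mask.grid


@dataclass
class FDRResult:
    """Benjamini–Hochberg decision over the eligible voxels."""

    q: float
    p_cutoff: float | None
    t_cutoff: float | None
    sig_mask: np.ndarray
    n_significant: int
    n_tests: int


@dataclass
class ClusterLabels:
    """Connected components of a significance mask."""

    labels: np.ndarray
    connectivity: int
    sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def voxelwise_t(
    cohort: LesionCohort,
    residuals,
    mask: AnalysisMask,
    lesion_class: str = "wml",
    alternative: str = "greater",
    welch: bool = False,
    domain: str | None = None,
) -> TMap:
    """Mass-univariate two-sample t-test of scores by lesion status.

    Parameters
    ----------
    residuals : pandas.Series
        Scores indexed by patient_id (typically covariate residuals of a
        domain composite); must cover every cohort patient.
    alternative : {"greater", "two-sided"}
        "greater" gives one-sided p in the deficit direction (lesioned
        worse, t > 0).
    welch : bool
        Use Welch's unequal-variance t instead of the pooled-variance
        (Student) default.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    y = np.asarray(residuals.reindex(list(cohort.patient_ids)), dtype=np.float64)
    if np.isnan(y).any():
        missing = [p for p, v in zip(cohort.patient_ids, y) if np.isnan(v)]
        raise ValueError(f"residual scores missing for patients: {missing[:5]}")

    flat_mask = np.asarray(mask.mask, dtype=bool).ravel()
    L = cohort.lesion_matrix(lesion_class, mask=mask.mask)  # (n, m) bool
    n = L.shape[0]
    n1 = L.sum(axis=0).astype(np.float64)  # lesioned
    n0 = n - n1
    if (n1 < 2).any() or (n0 < 2).any():
        raise ValueError(
            "analysis mask contains voxels with fewer than 2 lesioned or 2 intact "
            "patients; rebuild the mask from this cohort"
        )

    Lf = L.astype(np.float64)
    s1 = y @ Lf
    ss1 = (y * y) @ Lf
    s_tot = y.sum()
    ss_tot = float(y @ y)
    s0 = s_tot - s1
    ss0 = ss_tot - ss1
    m1 = s1 / n1
    m0 = s0 / n0
    sq1 = np.maximum(ss1 - n1 * m1**2, 0.0)
    sq0 = np.maximum(ss0 - n0 * m0**2, 0.0)

    if welch:
        v1 = sq1 / (n1 - 1)
        v0 = sq0 / (n0 - 1)
        se2 = v1 / n1 + v0 / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            dof = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
    else:
        dof = np.full_like(n1, n - 2)
        pooled = (sq1 + sq0) / (n - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n0)

    bad = ~(se2 > 0)
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} masked voxel(s) had zero pooled variance and were dropped",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m0 - m1) / np.sqrt(se2)
    t[bad] = np.nan
    if alternative == "greater":
        p = stats.t.sf(t, dof)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[bad] = np.nan

    shape = cohort.grid.shape
    t_full = np.full(shape, np.nan).ravel()
    p_full = np.full(shape, np.nan).ravel()
    df_full = np.zeros(shape, dtype=np.float64).ravel()
    valid = np.zeros(shape, dtype=bool).ravel()
    idx = np.flatnonzero(flat_mask)
    t_full[idx] = t
    p_full[idx] = p
    df_full[idx] = dof
    valid[idx] = ~bad
    return TMap(
        t=t_full.reshape(shape),
        p=p_full.reshape(shape),
        df=df_full.reshape(shape),
        valid=valid.reshape(shape),
        mask=mask,
        lesion_class=lesion_class,
        alternative=alternative,
        domain=domain,
        n_dropped_zero_variance=n_dropped,
    )


def bh_fdr(tmap: TMap, q: float = 0.05) -> FDRResult:
    """Benjamini–Hochberg FDR decision over the map's valid voxels.

    With sorted p-values p(1) <= ... <= p(m), the rejection index is
    k = max{i : p(i) <= i*q/m}; all voxels with p <= p(k) are declared
    significant.  If no index qualifies, nothing is rejected.  The
    equivalent t cutoff is the smallest t among significant voxels.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    valid = tmap.valid
    p = tmap.p[valid]
    if p.size == 0:
        raise ValueError("empty t-map: no valid voxels to threshold")
    m = p.size
    order = np.sort(p)
    thresh = np.arange(1, m + 1) * (q / m)
    passing = np.flatnonzero(order <= thresh)
    sig_mask = np.zeros(tmap.t.shape, dtype=bool)
    if passing.size == 0:
        return FDRResult(q=q, p_cutoff=None, t_cutoff=None, sig_mask=sig_mask,
                         n_significant=0, n_tests=m)
    p_cut = float(order[passing[-1]])
    sig_mask[valid] = tmap.p[valid] <= p_cut
    t_cut = float(np.min(tmap.t[sig_mask]))
    return FDRResult(
        q=q,
        p_cutoff=p_cut,
        t_cutoff=t_cut,
        sig_mask=sig_mask,
        n_significant=int(sig_mask.sum()),
        n_tests=m,
    )


def label_clusters(sig_mask: np.ndarray, connectivity: int = 26) -> ClusterLabels:
    """3D connected components of a binary mask (6/18/26-connectivity)."""
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    sig = np.asarray(sig_mask, dtype=bool)
    labels = measure.label(sig, connectivity=_CONNECTIVITY[connectivity])
    counts = np.bincount(labels.ravel())
    sizes = {int(lab): int(c) for lab, c in enumerate(counts) if lab > 0 and c > 0}
    return ClusterLabels(labels=labels, connectivity=connectivity, sizes=sizes)


class LesionSymptomMapper(BaseEstimator):
    """End-to-end VLSM for one lesion class and one score vector.

    Estimator-style wrapper: ``fit(cohort, residuals)`` computes the
    prevalence map, eligibility mask, voxel-wise t-map, FDR decision and
    cluster labels, stored as fitted attributes.

    Parameters
    ----------
    lesion_class : {"wml", "ll"}
    min_patients : int
        Minimum lesioned-patient count for a voxel to enter the analysis.
    q : float
        FDR level.
    alternative : {"greater", "two-sided"}
    connectivity : {6, 18, 26}
    welch : bool
    """

    def __init__(
        self,
        lesion_class: str = "wml",
        min_patients: int = 5,
        q: float = 0.05,
        alternative: str = "greater",
        connectivity: int = 26,
        welch: bool = False,
    ):
        self.lesion_class = lesion_class
        self.min_patients = min_patients
        self.q = q
        self.alternative = alternative
        self.connectivity = connectivity
        self.welch = welch

    def fit(self, cohort: LesionCohort, residuals):
        self.prevalence_ = prevalence_map(cohort, self.lesion_class)
        self.mask_ = analysis_mask(self.prevalence_, self.min_patients)
        if self.mask_.n_voxels == 0:
            raise InsufficientCoverageError(
                f"no voxel is affected in at least {self.min_patients} patients "
                f"for class {self.lesion_class!r}; VLSM cannot be performed"
            )
        self.tmap_ = voxelwise_t(
            cohort,
            residuals,
            self.mask_,
            lesion_class=self.lesion_class,
            alternative=self.alternative,
            welch=self.welch,
        )
        self.fdr_ = bh_fdr(self.tmap_, self.q)
        self.clusters_ = label_clusters(self.fdr_.sig_mask, self.connectivity)
        return self
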