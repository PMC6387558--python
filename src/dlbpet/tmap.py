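"""Voxel-wise hypometabolism t-maps against a normative database.

A single patient (or a patient group) is compared with the control
database by an ordinary least squares fit at every in-mask voxel of

    uptake ~ intercept + group_indicator + age

with age an optional nuisance covariate.  The reported statistic is the
*negated* t of the group indicator, so positive t means the test
subject(s) show LOWER uptake than controls (hypometabolism); only this
one-sided contrast is assessed.  Familywise error is controlled by
Bonferroni correction over the in-mask voxels, followed by a cluster
extent filter on the suprathreshold connected components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import SubjectScan

__all__ = ["TMap", "ClusterSet", "fit_subject_tmap", "fit_group_tmap",
           "fwe_threshold", "extract_clusters", "extent_voxels",
           "DEFAULT_EXTENT_MM3"]

#: Default cluster extent expressed as a physical volume: 100 voxels at
#: the 2 mm isotropic grid conventionally used by SPM analyses.
DEFAULT_EXTENT_MM3 = 100 * 2.0 ** 3


@dataclass
class TMap:
    """Voxel-wise t statistic volume (positive = hypometabolism)."""

    t: np.ndarray
    df: int
    mask: np.ndarray
    n_controls: int
    n_test: int
    used_age: bool
    voxel_size_mm: float
    alpha: float | None = None
    threshold: float | None = None
    fwe_method: str | None = None


@dataclass
class ClusterSet:
    """Suprathreshold connected components surviving the extent filter.

    ``labels`` is an integer volume with clusters numbered 1..C by
    decreasing voxel count; 0 is background.
    """

    labels: np.ndarray
    sizes: list[int]
    peak_t: list[float]
    peak_ijk: list[tuple[int, int, int]]
    k: int
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def suprathreshold(self) -> np.ndarray:
        return self.labels > 0


def _design(ages: np.ndarray, n_test: int, use_age: bool) -> np.ndarray:
    n = len(ages)
    cols = [np.ones(n), np.r_[np.zeros(n - n_test), np.ones(n_test)]]
    if use_age:
        cols.append(ages - ages.mean())
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient design matrix (constant ages with the age "
            "covariate requested, or no controls)")
    return X


def _fit(test_scans, controls, mask, use_age, ages):
    if len(controls) < 2:
        raise ValueError("need at least 2 control scans")
    shape = controls[0].volume.shape
    for s in list(controls) + list(test_scans):
        if s.volume.shape != shape:
            raise ValueError(
                f"grid mismatch: {s.subject_id} has shape {s.volume.shape}, "
                f"expected {shape}")
    if ages is None:
        ages = [s.age for s in controls] + [s.age for s in test_scans]
    ages = np.asarray(ages, dtype=float)
    n_test = len(test_scans)
    X = _design(ages, n_test, use_age)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")

    Y = np.stack([s.volume[mask] for s in list(controls) + list(test_scans)])
    Y = Y.astype(np.float64)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    # voxels fitted exactly (noise-free phantoms) have rss at rounding
    # level; treat them as zero-residual rather than dividing noise by it
    scale = max(float(np.abs(Y).max(initial=0.0)), 1.0)
    tiny = n * (np.finfo(float).eps * scale) ** 2 * 1e4
    exact = rss <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df * XtX_inv[1, 1])
        tvals = np.where(~exact & (se > 0), -B[1] / np.where(se > 0, se, 1.0),
                         0.0)
        b_tiny = np.abs(B[1]) <= np.sqrt(tiny)
        tvals = np.where(exact & ~b_tiny, -np.sign(B[1]) * np.inf, tvals)

    t = np.zeros(shape)
    t[mask] = tvals
    return TMap(t=t, df=df, mask=mask, n_controls=len(controls),
                n_test=n_test, used_age=use_age,
                voxel_size_mm=controls[0].voxel_size_mm)


def fit_subject_tmap(subject: SubjectScan, controls, mask, *,
                     use_age: bool = True, ages=None) -> TMap:
    """Single-subject hypometabolism t-map versus the control database.

    Ages default to those carried by the scans (controls first, subject
    last, matching an explicitly supplied ``ages`` vector).  Degrees of
    freedom are (N + 1) - rank of the design.
    """
    return _fit([subject], controls, mask, use_age, ages)


def fit_group_tmap(patients, controls, mask, *, use_age: bool = True,
                   ages=None) -> TMap:
    """Group hypometabolism t-map (patients vs controls)."""
    if len(patients) == 0:
        raise ValueError("empty patient group")
    return _fit(list(patients), controls, mask, use_age, ages)


def fwe_threshold(tmap: TMap, alpha: float = 0.05) -> float:
    """Bonferroni familywise-error t threshold.

    Upper-tail Student quantile at alpha / V with the map's degrees of
    freedom, V the number of in-mask voxels.  Conservative under the
    spatial correlation introduced by smoothing.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if tmap.df <= 0:
        raise ValueError("non-positive degrees of freedom")
    v = int(tmap.mask.sum())
    thr = float(stats.t.isf(alpha / v, tmap.df))
    tmap.alpha = alpha
    tmap.threshold = thr
    tmap.fwe_method = "bonferroni"
    return thr


_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            18: ndimage.generate_binary_structure(3, 2),
            26: ndimage.generate_binary_structure(3, 3)}


def extent_voxels(extent_mm3: float, voxel_size_mm: float) -> int:
    """Cluster extent in voxels for this grid, from a physical volume.

    The conventional extent of 100 voxels is tied to a 2 mm grid; on
    other grids the same physical volume is enforced (rounded up)."""
    return max(1, math.ceil(extent_mm3 / voxel_size_mm ** 3 - 1e-9))


def extract_clusters(tmap: TMap, t_threshold: float, k: int | None = None, *,
                     connectivity: int = 18, strict_gt: bool = False,
                     extent_mm3: float = DEFAULT_EXTENT_MM3) -> ClusterSet:
    """Connected components of {t >= threshold} at least k voxels large.

    ``k`` defaults to the voxel count matching ``extent_mm3`` on the
    map's grid.  Components are relabeled 1..C by decreasing size (ties
    by ascending original scan order).  With ``strict_gt`` components of
    exactly k voxels are discarded instead of kept.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if k is None:
        k = extent_voxels(extent_mm3, tmap.voxel_size_mm)
    if k < 1:
        raise ValueError("k must be >= 1")
    supra = (tmap.t >= t_threshold) & tmap.mask
    lab, n = ndimage.label(supra, structure=_STRUCTS[connectivity])
    keep = []
    for i in range(1, n + 1):
        size = int((lab == i).sum())
        if size > k or (size == k and not strict_gt):
            keep.append((size, i))
    keep.sort(key=lambda x: (-x[0], x[1]))

    out = np.zeros_like(lab)
    sizes, peak_t, peak_ijk = [], [], []
    for new, (size, old) in enumerate(keep, start=1):
        m = lab == old
        out[m] = new
        sizes.append(size)
        tm = np.where(m, tmap.t, -np.inf)
        pk = np.unravel_index(int(np.argmax(tm)), tm.shape)
        peak_t.append(float(tmap.t[pk]))
        peak_ijk.append(tuple(int(c) for c in pk))
    return ClusterSet(labels=out, sizes=sizes, peak_t=peak_t,
                      peak_ijk=peak_ijk, k=k, connectivity=connectivity)
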