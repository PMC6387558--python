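"""Metabolic subtype discovery.

From each subject's single-subject t-map the mean (unthresholded) t is
extracted over the 14 analysis ROIs, giving a subjects x 14 severity
matrix.  The matrix is reduced by PCA, and the component scores enter an
agglomerative hierarchical clustering that combines supremum-norm
(Chebyshev) dissimilarities with the Ward criterion via the
Lance-Williams recurrence applied to squared dissimilarities.  Ward on a
non-Euclidean dissimilarity is formally improper, but the combination is
the analysis this package reproduces, so it is implemented exactly and
the limitation is documented rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .diagstats import pearson_chi2, welch_t
from .phantom import ROI_NAMES, AtlasROIs

__all__ = ["FeatureMatrix", "Dendrogram", "build_feature_matrix",
           "pca_reduce", "hcluster_chebyshev_ward", "cut",
           "subgroup_compare", "silhouette_profile", "to_newick"]


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x 14-ROI mean-t hypometabolism severities."""

    values: np.ndarray
    subject_ids: list[str]
    roi_names: tuple[str, ...] = ROI_NAMES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=list(self.roi_names))


@dataclass(frozen=True)
class Dendrogram:
    """Merge sequence in the standard linkage-table convention.

    ``linkage`` has one row per merge: (cluster id 1, cluster id 2,
    height, new size), original observations numbered 0..n-1 and the
    cluster created at step i numbered n + i.  Heights are on the
    root-of-squared-dissimilarity scale of the Ward recurrence.
    """

    linkage: np.ndarray
    n: int
    subject_ids: list[str] | None = None


def build_feature_matrix(tmaps, atlas: AtlasROIs,
                         subject_ids=None) -> FeatureMatrix:
    """Mean unthresholded t per ROI (in-mask voxels only) per subject."""
    rows = []
    for tm in tmaps:
        row = []
        for roi in ROI_NAMES:
            m = atlas.mask(roi) & tm.mask
            if not m.any():
                raise ValueError(f"ROI {roi!r} lies entirely outside the "
                                 "analysis mask")
            row.append(float(tm.t[m].mean()))
        rows.append(row)
    values = np.asarray(rows, dtype=float)
    if subject_ids is None:
        subject_ids = [f"s{i + 1:03d}" for i in range(len(rows))]
    return FeatureMatrix(values=values, subject_ids=list(subject_ids))


def pca_reduce(matrix, variance_target: float = 0.80, *,
               standardize: bool = True) -> np.ndarray:
    """PCA scores keeping the fewest components reaching the variance target.

    Columns are centered and, by default, scaled to unit variance
    (constant columns are left unscaled).  Components come from the
    eigendecomposition of the covariance of the processed matrix; the
    smallest number of leading components whose cumulative explained
    variance is >= ``variance_target`` is kept.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    X = np.asarray(getattr(matrix, "values", matrix), dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects for PCA")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    # thin SVD; deterministic sign convention (largest |loading| positive)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    ev = s ** 2
    if ev.sum() == 0:
        return np.zeros((X.shape[0], 1))
    ratio = np.cumsum(ev) / ev.sum()
    n_comp = int(np.searchsorted(ratio, variance_target - 1e-12) + 1)
    signs = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = u * s
    return scores[:, :n_comp] * signs[:n_comp]


def _ward_update(d, sizes, i, j, k):
    ni, nj, nk = sizes[i], sizes[j], sizes[k]
    return ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * d[i, j]) / (
        ni + nj + nk)


def hcluster_chebyshev_ward(scores) -> Dendrogram:
    """Agglomerate with Ward's criterion on squared Chebyshev distances.

    The Lance-Williams Ward recurrence is applied to the squared
    supremum-norm dissimilarity matrix; reported merge heights are the
    square roots of the Ward dissimilarities (matching the common
    linkage convention), and are non-decreasing.  Ties are broken toward
    the pair with the lowest cluster indices.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    d = squareform(pdist(X, metric="chebyshev") ** 2)

    # active clusters keyed by linkage id; distance matrix grows as
    # merged clusters get fresh ids n, n+1, ...
    big = np.full((2 * n - 1, 2 * n - 1), np.inf)
    big[:n, :n] = d
    np.fill_diagonal(big, np.inf)
    sizes = np.zeros(2 * n - 1, dtype=int)
    sizes[:n] = 1
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (big[i, j], i, j)
                if best is None or key < best:
                    best = key
        dist, i, j = best
        new = n + step
        for k in active:
            if k in (i, j):
                continue
            big[new, k] = big[k, new] = _ward_update(big, sizes, i, j, k)
        sizes[new] = sizes[i] + sizes[j]
        active = [a for a in active if a not in (i, j)] + [new]
        Z[step] = (i, j, np.sqrt(max(dist, 0.0)), sizes[new])
    ids = getattr(scores, "subject_ids", None)
    return Dendrogram(linkage=Z, n=n, subject_ids=ids)


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat labels from removing the k - 1 highest merges.

    Labels are 1..k with label 1 the largest subgroup (ties broken by
    the smallest member index).
    """
    n = dendrogram.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):  # all but the k-1 highest merges
        i, j = int(dendrogram.linkage[step, 0]), int(dendrogram.linkage[step, 1])
        new = n + step
        parent[find(i)] = new
        parent[find(j)] = new
    roots = [find(i) for i in range(n)]
    groups: dict[int, list[int]] = {}
    for idx, r in enumerate(roots):
        groups.setdefault(r, []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    labels = np.zeros(n, dtype=int)
    for lab, members in enumerate(ordered, start=1):
        labels[members] = lab
    return labels


def silhouette_profile(scores, dendrogram: Dendrogram, ks=range(2, 7)):
    """Mean silhouette (Chebyshev metric) of the flat cuts, as guidance
    for choosing the number of subtypes."""
    from sklearn.metrics import silhouette_score

    X = np.asarray(scores, dtype=float)
    out = {}
    for k in ks:
        if not 2 <= k < dendrogram.n:
            continue
        labels = cut(dendrogram, k)
        out[int(k)] = float(silhouette_score(X, labels, metric="chebyshev"))
    return out


def subgroup_compare(labels, clinical: pd.DataFrame, *, binary_cols=(),
                     continuous_cols=()) -> pd.DataFrame:
    """Compare two subgroups feature by feature.

    Binary features (0/1 per subject) are tested with the uncorrected
    Pearson chi-square on the 2x2 counts; continuous features with
    Welch's t-test.  Returns one row per feature.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("need exactly two subgroups")
    g1, g2 = labels == uniq[0], labels == uniq[1]
    rows = []
    for col in binary_cols:
        x = clinical[col].to_numpy()
        table = [[int(x[g1].sum()), int(g1.sum() - x[g1].sum())],
                 [int(x[g2].sum()), int(g2.sum() - x[g2].sum())]]
        stat, p = pearson_chi2(table)
        rows.append((col, "binary", float(x[g1].mean()), float(x[g2].mean()),
                     stat, p))
    for col in continuous_cols:
        x = clinical[col].to_numpy(dtype=float)
        if g1.sum() < 2 or g2.sum() < 2:
            raise ValueError("subgroup too small for a t-test")
        stat, _, p = welch_t(x[g1], x[g2])
        rows.append((col, "continuous", float(x[g1].mean()),
                     float(x[g2].mean()), stat, p))
    return pd.DataFrame(rows, columns=["feature", "type", "group1", "group2",
                                       "statistic", "p"])


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization of the merge tree (branch lengths from merge
    heights)."""
    n = dendrogram.n
    ids = dendrogram.subject_ids or [f"s{i + 1:03d}" for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    node = {i: ids[i] for i in range(n)}
    for step in range(n - 1):
        i, j, h, _ = dendrogram.linkage[step]
        i, j = int(i), int(j)
        bi, bj = h - height[i], h - height[j]
        node[n + step] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";"
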