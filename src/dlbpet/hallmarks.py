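"""Discriminative hypometabolism hallmarks.

Four features distinguish DLB from its differential diagnoses on a
single-subject scan: (i) occipital hypometabolism, (ii) the cingulate
island sign (CIS) — relative preservation of posterior cingulate uptake
amid precuneus/cuneus hypometabolism, quantified as the ratio of the
posterior-cingulate ROI mean to the sum of the precuneus and cuneus ROI
means, (iii) dorsolateral prefrontal (DLPFC) hypometabolism, and
(iv) hypometabolism asymmetry.

Regional "presence of hypometabolism" is operationalised as the fraction
of a composite ROI covered by extent-filtered suprathreshold cluster
voxels reaching a configurable minimum (default 2%), which is robust to
single stray voxels.  Asymmetry is the normalised left/right difference
of suprathreshold voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import COMPOSITES, ROI_NAMES, AtlasROIs, SubjectScan
from .tmap import ClusterSet

__all__ = ["HallmarkProfile", "roi_involvement", "cingulate_island_sign",
           "cis_cutoff", "asymmetry_index", "compute_hallmarks", "roc_auc"]


@dataclass(frozen=True)
class HallmarkProfile:
    """Per-subject hallmark summary."""

    subject_id: str
    occipital_involved: bool
    dlpfc_involved: bool
    cis_value: float
    asymmetry_index: float
    symmetric: bool
    roi_fractions: dict[str, float]
    composite_fractions: dict[str, float]


def _suprathreshold_fraction(clusters: ClusterSet, roi_mask: np.ndarray) -> float:
    denom = int(roi_mask.sum())
    if denom == 0:
        raise ValueError("empty ROI mask")
    return float((clusters.suprathreshold & roi_mask).sum()) / denom


def roi_involvement(clusters: ClusterSet, atlas: AtlasROIs, roi_names,
                    min_fraction: float = 0.02) -> bool:
    """True iff the composite ROI's suprathreshold fraction reaches
    ``min_fraction``.  ``roi_names`` may be a composite name, one ROI
    name, or an iterable of ROI names."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    if isinstance(roi_names, str) and roi_names in COMPOSITES:
        roi_names = COMPOSITES[roi_names]
    elif isinstance(roi_names, str):
        roi_names = (roi_names,)
    mask = atlas.composite(roi_names)
    return _suprathreshold_fraction(clusters, mask) >= min_fraction


def cingulate_island_sign(scaled_scan: SubjectScan, atlas: AtlasROIs) -> float:
    """CIS = mean(posterior cingulate) / (mean(precuneus) + mean(cuneus)).

    A ratio of regional means of the globally scaled uptake image; it is
    invariant to any positive rescaling of the input, so the global
    scaling target drops out.  Around 0.5 for a uniform scan; higher when
    the posterior cingulate is spared relative to precuneus and cuneus.
    """
    vol = scaled_scan.volume
    pcc = float(vol[atlas.mask("posterior_cingulate")].mean())
    denom = (float(vol[atlas.mask("precuneus")].mean())
             + float(vol[atlas.mask("cuneus")].mean()))
    if denom <= 0:
        raise ValueError("zero precuneus+cuneus uptake")
    return pcc / denom


def roc_auc(positives, negatives) -> float:
    """AUC by the Mann-Whitney identity (ties count one half)."""
    a = np.asarray(positives, dtype=float)[:, None]
    b = np.asarray(negatives, dtype=float)[None, :]
    return float(((a > b).sum() + 0.5 * (a == b).sum()) / (a.size * b.size))


def cis_cutoff(cis_positive, cis_negative):
    """Optimal CIS cutoff and AUC for a high-CIS-positive classifier.

    Candidate cutoffs are the midpoints between adjacent sorted unique
    pooled values; the returned cutoff maximises Youden's J =
    sensitivity + specificity - 1 (a subject is called positive when its
    CIS is >= the cutoff).  Ties are broken toward higher sensitivity,
    then toward the lower cutoff.
    """
    pos = np.asarray(cis_positive, dtype=float)
    neg = np.asarray(cis_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be nonempty")
    auc = roc_auc(pos, neg)
    uniq = np.unique(np.concatenate([pos, neg]))
    if uniq.size == 1:
        return float(uniq[0]), auc
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for c in cands:
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        key = (sens + spec - 1.0, sens, -c)
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1], auc


def asymmetry_index(clusters: ClusterSet, atlas: AtlasROIs,
                    tau: float = 0.5):
    """Normalised left/right suprathreshold imbalance.

    AI = |nL - nR| / max(1, nL + nR) over extent-filtered suprathreshold
    voxels; the subject is symmetric when AI <= tau.  An empty map has
    AI = 0 and is symmetric.
    """
    supra = clusters.suprathreshold
    n_l = int((supra & atlas.left).sum())
    n_r = int((supra & atlas.right).sum())
    ai = abs(n_l - n_r) / max(1, n_l + n_r)
    return float(ai), ai <= tau


def compute_hallmarks(scaled_scan: SubjectScan, clusters: ClusterSet,
                      atlas: AtlasROIs, *, min_fraction: float = 0.02,
                      tau: float = 0.5) -> HallmarkProfile:
    """Full hallmark profile for one subject."""
    roi_fractions = {r: _suprathreshold_fraction(clusters, atlas.mask(r))
                     for r in ROI_NAMES}
    composite_fractions = {
        c: _suprathreshold_fraction(clusters, atlas.composite(c))
        for c in COMPOSITES}
    ai, symmetric = asymmetry_index(clusters, atlas, tau)
    return HallmarkProfile(
        subject_id=scaled_scan.subject_id,
        occipital_involved=composite_fractions["occipital"] >= min_fraction,
        dlpfc_involved=composite_fractions["dlpfc"] >= min_fraction,
        cis_value=cingulate_island_sign(scaled_scan, atlas),
        asymmetry_index=ai,
        symmetric=symmetric,
        roi_fractions=roi_fractions,
        composite_fractions=composite_fractions,
    )
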