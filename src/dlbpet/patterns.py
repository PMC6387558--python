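"""Rule-based classification of hypometabolism topographies.

A deterministic decision list maps a subject's regional involvement
profile to one of the disease-like pattern labels (DLB-like, AD-like,
PCA-like, PD-like) or to "negative".  Four parameterizations of the rule
— differing in the involvement threshold and the asymmetry tolerance —
stand in for four independent expert raters; their labels are combined
by a supermajority vote (3 of 4 by default), falling back to a
"discordant" verdict with the plurality label recorded for adjudication.

Decision list (first match wins):

1. no composite involved anywhere                        -> NEGATIVE
2. involvement confined to premotor/motor cortex         -> PD_LIKE
3. occipital AND temporo-parietal involved:
       frontal-eye-field involved AND asymmetric
       AND DLPFC spared                                  -> PCA_LIKE
       otherwise                                         -> DLB_LIKE
4. temporo-parietal and/or posterior cingulate/precuneus
   involved without occipital involvement                -> AD_LIKE
5. otherwise: label of the most-involved composite, ties
   broken in the fixed order DLB > AD > PCA > PD
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .hallmarks import HallmarkProfile, compute_hallmarks
from .phantom import AtlasROIs, SubjectScan
from .tmap import ClusterSet

__all__ = ["PatternLabel", "RaterRule", "DEFAULT_RATERS", "VoteResult",
           "classify_pattern", "classify_subject", "rate_subject",
           "supermajority_vote", "mean_pairwise_kappa"]


class PatternLabel(str, Enum):
    DLB_LIKE = "DLB_LIKE"
    AD_LIKE = "AD_LIKE"
    PCA_LIKE = "PCA_LIKE"
    PD_LIKE = "PD_LIKE"
    NEGATIVE = "NEGATIVE"
    DISCORDANT = "DISCORDANT"


#: Fixed tie-break order for votes and rule 5.
_LABEL_ORDER = (PatternLabel.DLB_LIKE, PatternLabel.AD_LIKE,
                PatternLabel.PCA_LIKE, PatternLabel.PD_LIKE,
                PatternLabel.NEGATIVE)


@dataclass(frozen=True)
class RaterRule:
    """One rater variant: an involvement threshold and asymmetry tolerance."""

    min_fraction: float = 0.02
    tau: float = 0.5
    variant_id: str = "default"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")


#: Four rater variants standing in for four human experts.
DEFAULT_RATERS = (
    RaterRule(0.01, 0.4, "r1"),
    RaterRule(0.02, 0.5, "r2"),
    RaterRule(0.02, 0.5, "r3"),
    RaterRule(0.05, 0.6, "r4"),
)

#: Composite -> label for the rule-5 fallback.
_COMPOSITE_LABEL = {
    "occipital": PatternLabel.DLB_LIKE,
    "temporo_parietal": PatternLabel.AD_LIKE,
    "pcc_precuneus": PatternLabel.AD_LIKE,
    "dlpfc": PatternLabel.DLB_LIKE,
    "frontal_eye_field": PatternLabel.PCA_LIKE,
    "premotor_motor": PatternLabel.PD_LIKE,
}


def classify_pattern(composite_fractions: dict[str, float],
                     asymmetry: float, rule: RaterRule) -> PatternLabel:
    """Apply the decision list to one subject's involvement profile.

    ``composite_fractions`` maps each composite region to its
    suprathreshold fraction; ``asymmetry`` is the AI of the map.  Pure
    function: identical inputs give identical labels.
    """
    inv = {c: f >= rule.min_fraction for c, f in composite_fractions.items()}
    asymmetric = asymmetry > rule.tau

    if not any(inv.values()):
        return PatternLabel.NEGATIVE
    if inv["premotor_motor"] and not any(
            v for c, v in inv.items() if c != "premotor_motor"):
        return PatternLabel.PD_LIKE
    if inv["occipital"] and inv["temporo_parietal"]:
        if inv["frontal_eye_field"] and asymmetric and not inv["dlpfc"]:
            return PatternLabel.PCA_LIKE
        return PatternLabel.DLB_LIKE
    if (inv["temporo_parietal"] or inv["pcc_precuneus"]) and not inv["occipital"]:
        return PatternLabel.AD_LIKE
    # rule 5: most-involved composite, ties by fixed label order
    order = {lab: i for i, lab in enumerate(_LABEL_ORDER)}
    best = max(composite_fractions,
               key=lambda c: (composite_fractions[c],
                              -order[_COMPOSITE_LABEL[c]]))
    return _COMPOSITE_LABEL[best]


def classify_subject(profile: HallmarkProfile, rule: RaterRule) -> PatternLabel:
    """Classify from a hallmark profile computed under any thresholds.

    The rule re-applies its own ``min_fraction``/``tau`` to the stored
    fractions, so one hallmark pass serves every rater variant.
    """
    return classify_pattern(profile.composite_fractions,
                            profile.asymmetry_index, rule)


def rate_subject(scaled_scan: SubjectScan, clusters: ClusterSet,
                 atlas: AtlasROIs,
                 raters=DEFAULT_RATERS) -> list[PatternLabel]:
    """Labels from every rater variant for one subject."""
    profile = compute_hallmarks(scaled_scan, clusters, atlas)
    return [classify_subject(profile, r) for r in raters]


@dataclass(frozen=True)
class VoteResult:
    label: PatternLabel
    fallback: PatternLabel  # plurality label, used to adjudicate discordance


def supermajority_vote(labels, quorum: int = 3) -> VoteResult:
    """Aggregate rater labels; DISCORDANT when no label reaches quorum."""
    labels = [PatternLabel(l) for l in labels]
    if not labels:
        raise ValueError("empty label list")
    if len(labels) < 3:
        raise ValueError("need at least 3 rater labels")
    if quorum <= len(labels) / 2:
        raise ValueError("quorum must exceed half of the raters")
    order = {lab: i for i, lab in enumerate(_LABEL_ORDER)}
    counts: dict[PatternLabel, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    plurality = max(counts, key=lambda l: (counts[l], -order[l]))
    if counts[plurality] >= quorum:
        return VoteResult(plurality, plurality)
    return VoteResult(PatternLabel.DISCORDANT, plurality)


def mean_pairwise_kappa(label_matrix) -> float:
    """Mean Cohen's kappa over all rater pairs.

    ``label_matrix`` is raters x subjects.  Pairs with an undefined
    kappa (zero chance-corrected denominator, e.g. a rater using one
    constant label matched by chance agreement 1) are excluded with a
    warning.
    """
    mat = np.asarray([[str(PatternLabel(l).value) for l in row]
                      for row in label_matrix], dtype=object)
    n_raters, n_subj = mat.shape
    if n_raters < 2 or n_subj < 2:
        raise ValueError("need >= 2 raters and >= 2 subjects")
    kappas = []
    for i, j in itertools.combinations(range(n_raters), 2):
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns before we do
            k = cohen_kappa_score(mat[i], mat[j])
        if np.isnan(k):
            warnings.warn(
                f"kappa undefined for rater pair ({i}, {j}); excluded",
                stacklevel=2)
        else:
            kappas.append(float(k))
    if not kappas:
        raise ValueError("kappa undefined for every rater pair")
    return float(np.mean(kappas))
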