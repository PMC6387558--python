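"""Published counts from the original clinical study, and their recomputation.

The clinical scans behind the study this pipeline re-implements were
never deposited, but the prevalence counts of its classification tables
were published.  This module ships those counts as plain inputs and
recomputes every derivable statistic — pairwise diagnostic performance
with exact intervals, hallmark performance, agreement and relative gain,
McNemar, and the subgroup chi-squares — through the same functions the
pipeline applies to synthetic cohorts.

Cohorts: DLB (n=72), ADD (Alzheimer's disease dementia, n=60, including
5 posterior-cortical-atrophy variants), PD (n=36); a normative database
of 112 controls stands behind the t-maps but contributes no counts here.
"""

from __future__ import annotations

from . import diagstats

__all__ = ["PATTERN_COUNTS", "HALLMARK_COUNTS", "AGREEMENT",
           "MCNEMAR_DISCORDANTS", "SUBGROUP_VH", "expand_labels",
           "pattern_performance", "hallmark_performance",
           "predictive_performance", "subgroup_chi_squares",
           "all_reference_stats"]

#: Rater-voted pattern label counts per clinical cohort.
PATTERN_COUNTS = {
    "DLB": {"DLB_LIKE": 64, "AD_LIKE": 8, "PD_LIKE": 0, "n": 72},
    "ADD": {"DLB_LIKE": 3, "AD_LIKE": 57, "PD_LIKE": 0, "n": 60},
    "PD": {"DLB_LIKE": 5, "AD_LIKE": 0, "PD_LIKE": 31, "n": 36},
}

#: Hallmark prevalence (present, n) per cohort.  The symmetry hallmark
#: counts subjects with a symmetric hypometabolism map; CIS counts
#: subjects with the sign present.  Hallmarks not evaluated for PD are
#: absent.
HALLMARK_COUNTS = {
    "occipital": {"DLB": (66, 72), "ADD": (5, 60), "PD": (5, 36)},
    "cis": {"DLB": (57, 72), "ADD": (22, 60)},
    "dlpfc": {"DLB": (31, 72), "ADD": (10, 60), "PD": (2, 36)},
    "symmetry": {"DLB": (71, 72), "ADD": (47, 60)},
}

#: Correct DLB classifications among the 72 patients: at the first
#: clinical assessment vs by the imaging classification alone.
AGREEMENT = {"entry_correct": 44, "test_correct": 64, "n": 72}

#: Discordant pairs (entry-only correct, imaging-only correct) for the
#: McNemar comparison, reconstructed from the published statistic under
#: the marginal constraint c - b = 64 - 44.
MCNEMAR_DISCORDANTS = (5, 25)

#: Visual-hallucination counts in the two metabolic subgroups
#: (severe-occipital n=31, milder-occipital n=41): prevalence at
#: follow-up, and conversion among patients free of hallucinations at
#: baseline.
SUBGROUP_VH = {
    "followup": {"severe": (29, 31), "milder": (26, 41)},
    "conversion": {"severe": (11, 13), "milder": (8, 23)},
}


def expand_labels():
    """Per-subject (label, cohort) lists reconstructed from the counts."""
    labels, truth = [], []
    for cohort, counts in PATTERN_COUNTS.items():
        other = counts["n"] - sum(v for k, v in counts.items() if k != "n")
        for lab in ("DLB_LIKE", "AD_LIKE", "PD_LIKE"):
            labels += [lab] * counts[lab]
            truth += [cohort] * counts[lab]
        labels += ["NEGATIVE"] * other
        truth += [cohort] * other
    return labels, truth


def pattern_performance():
    """Pairwise diagnostic performance of the voted pattern labels."""
    labels, truth = expand_labels()
    out = {}
    for a, b in (("DLB", "ADD"), ("DLB", "PD")):
        conf = diagstats.pairwise_confusion(
            labels, truth, a, b,
            label_map={"DLB": "DLB_LIKE", "ADD": "AD_LIKE", "PD": "PD_LIKE"})
        out[f"{a}_vs_{b}"] = diagstats.performance(conf)
    return out


def hallmark_performance():
    """Diagnostic performance of each hallmark, DLB vs ADD and DLB vs PD.

    The hallmark present in the DLB cohort counts as a positive test;
    comparison cohorts lacking it supply the true negatives."""
    out = {}
    for hallmark, groups in HALLMARK_COUNTS.items():
        kd, nd = groups["DLB"]
        for other in ("ADD", "PD"):
            if other not in groups:
                continue
            ko, no = groups[other]
            conf = diagstats.Confusion2x2(tp=kd, fn=nd - kd,
                                          tn=no - ko, fp=ko)
            out[f"{hallmark}_DLB_vs_{other}"] = diagstats.performance(conf)
    return out


def predictive_performance():
    """Agreement with the follow-up diagnosis, relative gain, McNemar."""
    p_entry, p_test, gain = diagstats.agreement_and_gain(
        AGREEMENT["entry_correct"], AGREEMENT["test_correct"], AGREEMENT["n"])
    stat, p = diagstats.mcnemar(*MCNEMAR_DISCORDANTS,
                                continuity_corrected=True)
    return {"entry_agreement": p_entry, "test_agreement": p_test,
            "relative_gain": gain, "mcnemar_chi2": stat, "mcnemar_p": p}


def subgroup_chi_squares():
    """Subgroup visual-hallucination chi-squares from the counts."""
    out = {}
    for key, groups in SUBGROUP_VH.items():
        ks, ns = groups["severe"]
        km, nm = groups["milder"]
        stat, p = diagstats.pearson_chi2([[ks, ns - ks], [km, nm - km]])
        out[key] = (stat, p)
    return out


def all_reference_stats() -> dict:
    """Flat dict of every statistic recomputable from the published counts."""
    out: dict[str, float] = {}
    for pair, perf in pattern_performance().items():
        out[f"{pair}_sensitivity"] = perf.sensitivity
        out[f"{pair}_specificity"] = perf.specificity
        out[f"{pair}_accuracy"] = perf.accuracy
    for key, perf in hallmark_performance().items():
        out[f"{key}_sensitivity"] = perf.sensitivity
        out[f"{key}_specificity"] = perf.specificity
        out[f"{key}_accuracy"] = perf.accuracy
    pred = predictive_performance()
    out["entry_agreement_pct"] = 100.0 * pred["entry_agreement"]
    out["test_agreement_pct"] = 100.0 * pred["test_agreement"]
    out["relative_gain_pct"] = 100.0 * pred["relative_gain"]
    out["mcnemar_chi2"] = pred["mcnemar_chi2"]
    chis = subgroup_chi_squares()
    out["vh_followup_chi2"] = chis["followup"][0]
    out["vh_conversion_chi2"] = chis["conversion"][0]
    return out
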