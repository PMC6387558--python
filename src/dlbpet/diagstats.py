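"""Diagnostic accuracy and comparison statistics.

2x2 diagnostic performance with exact Clopper-Pearson intervals,
pairwise-cohort confusion with third-pattern exclusion, ROC/AUC with the
DeLong paired test, McNemar's test for paired proportions, uncorrected
Pearson chi-square, agreement/relative-gain arithmetic, and Welch's
two-sample t-test (from samples or summary statistics).

Conventions: Pearson chi-square is computed WITHOUT Yates continuity
correction; McNemar defaults to the continuity-corrected statistic;
proportion intervals are exact (Clopper-Pearson, beta-quantile form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["Confusion2x2", "PerformanceResult", "pairwise_confusion",
           "performance", "clopper_pearson", "agreement_and_gain",
           "pearson_chi2", "mcnemar", "delong_paired", "welch_t",
           "counts_from_percent"]


@dataclass(frozen=True)
class Confusion2x2:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class PerformanceResult:
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]

    def rounded(self, ndigits: int = 2) -> dict:
        """Half-up rounding for report comparison."""
        def r(x):
            return float(np.floor(x * 10 ** ndigits + 0.5) / 10 ** ndigits)
        return {
            "sensitivity": r(self.sensitivity),
            "specificity": r(self.specificity),
            "accuracy": r(self.accuracy),
            "sensitivity_ci": (r(self.sensitivity_ci[0]), r(self.sensitivity_ci[1])),
            "specificity_ci": (r(self.specificity_ci[0]), r(self.specificity_ci[1])),
            "accuracy_ci": (r(self.accuracy_ci[0]), r(self.accuracy_ci[1])),
        }


def pairwise_confusion(labels, truth, disease_a: str, disease_b: str, *,
                       label_map=None) -> Confusion2x2:
    """Head-to-head confusion between two cohorts.

    Restricts to subjects whose true cohort is ``disease_a`` or
    ``disease_b`` AND whose assigned label is the A-like or B-like
    pattern; subjects labeled with a third pattern are excluded.  A-like
    labels in cohort A are true positives.
    """
    if label_map is None:
        label_map = {disease_a: f"{disease_a}_LIKE",
                     disease_b: f"{disease_b}_LIKE"}
    la, lb = label_map[disease_a], label_map[disease_b]
    tp = fn = tn = fp = 0
    for lab, tru in zip(labels, truth, strict=True):
        lab = getattr(lab, "value", lab)
        if tru == disease_a:
            if lab == la:
                tp += 1
            elif lab == lb:
                fn += 1
        elif tru == disease_b:
            if lab == lb:
                tn += 1
            elif lab == la:
                fp += 1
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError(
            f"no usable subjects for {disease_a} vs {disease_b} after "
            "third-pattern exclusion")
    return Confusion2x2(tp=tp, fn=fn, tn=tn, fp=fp)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval (beta-quantile form)."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    a = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def performance(conf: Confusion2x2, ci_conf: float = 0.95) -> PerformanceResult:
    """Sensitivity, specificity, accuracy with exact 95% intervals."""
    pos, neg = conf.tp + conf.fn, conf.tn + conf.fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be represented")
    return PerformanceResult(
        sensitivity=conf.tp / pos,
        specificity=conf.tn / neg,
        accuracy=(conf.tp + conf.tn) / conf.total,
        sensitivity_ci=clopper_pearson(conf.tp, pos, ci_conf),
        specificity_ci=clopper_pearson(conf.tn, neg, ci_conf),
        accuracy_ci=clopper_pearson(conf.tp + conf.tn, conf.total, ci_conf),
    )


def agreement_and_gain(correct_at_entry: int, correct_by_test: int, n: int):
    """Agreement proportions and the relative gain of the test.

    Returns (entry proportion, test proportion, relative gain), with
    relative gain = (correct_by_test - correct_at_entry) / correct_at_entry.
    """
    if not (0 <= correct_at_entry <= n and 0 <= correct_by_test <= n):
        raise ValueError("counts must lie in [0, n]")
    if correct_at_entry == 0:
        raise ValueError("relative gain undefined when no entry "
                         "classification is correct")
    return (correct_at_entry / n, correct_by_test / n,
            (correct_by_test - correct_at_entry) / correct_at_entry)


def pearson_chi2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square for a 2x2 table.

    statistic = N (ad - bc)^2 / (r1 r2 c1 c2); p from chi-square, df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    (a, b), (c, d) = t
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin")
    n = t.sum()
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, 1))


def mcnemar(b_discordant: int, c_discordant: int,
            continuity_corrected: bool = True) -> tuple[float, float]:
    """McNemar's test from the two discordant-pair counts."""
    b, c = b_discordant, c_discordant
    if b < 0 or c < 0 or b + c == 0:
        raise ValueError("need nonnegative discordant counts with b + c > 0")
    if continuity_corrected:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    return float(stat), float(stats.chi2.sf(stat, 1))


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    pos, neg = scores[truth], scores[~truth]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)  # V10 (per pos), V01 (per neg)


def delong_paired(scores1, scores2, binary_truth):
    """DeLong test for two correlated AUCs on the same subjects.

    Returns (auc1, auc2, Z, p).  AUCs use the Mann-Whitney identity;
    the variance of the AUC difference comes from the empirical
    covariance of the DeLong structural components.  Degenerate variance
    (e.g. identical score vectors) gives Z = 0, p = 1 by convention.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(binary_truth, dtype=bool)
    if s1.shape != y.shape or s2.shape != y.shape:
        raise ValueError("scores and truth must have identical shape")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v10_1, v01_1 = _delong_components(s1, y)
    v10_2, v01_2 = _delong_components(s2, y)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    # 1 - V01 averages to the AUC as well; cov() wants >= 2 observations
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_1, v10_2]))
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_1, v01_2]))
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return auc1, auc2, 0.0, 1.0
    z = (auc1 - auc2) / np.sqrt(var)
    return auc1, auc2, float(z), float(2 * stats.norm.sf(abs(z)))


def welch_t(group1=None, group2=None, *, summaries=None):
    """Welch's unequal-variance two-sample t-test.

    Either pass two sample arrays, or ``summaries=((m1, sd1, n1),
    (m2, sd2, n2))``.  Returns (t, df, p), two-sided.
    """
    if summaries is not None:
        (m1, sd1, n1), (m2, sd2, n2) = summaries
    else:
        g1 = np.asarray(group1, dtype=float)
        g2 = np.asarray(group2, dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise ValueError("need n >= 2 per group")
        m1, sd1, n1 = g1.mean(), g1.std(ddof=1), g1.size
        m2, sd2, n2 = g2.mean(), g2.std(ddof=1), g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def counts_from_percent(percent: float, n: int) -> int:
    """Reconstruct an integer count from a printed percentage."""
    return int(np.floor(percent / 100.0 * n + 0.5))
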