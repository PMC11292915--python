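"""Evaluation statistics: ROC/AUC with DeLong variance and paired test,
Youden cutoff, confusion metrics, calibration (Hosmer–Lemeshow), decision
curves, and 2×2 cohort-comparability tests.

AUC is the Mann–Whitney probability (ties count one half), identical to the
trapezoidal ROC area.  DeLong's variance and paired covariance come from
placement values (structural components), so the paired test accounts for
the correlation between two scores evaluated on the same patients.
Classification uses the fixed rule ``score ≥ cutoff → positive``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "CutoffResult",
    "ConfusionMetrics",
    "CalibrationResult",
    "NetBenefitCurve",
    "roc_auc",
    "delong_test",
    "youden_cutoff",
    "confusion_metrics",
    "confusion_at_cutoff",
    "hosmer_lemeshow",
    "decision_curve",
    "two_by_two_tests",
]


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-observation placement values V10 (positives), V01
    (negatives): the fraction of the other class each observation beats,
    ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank construction
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


@dataclass
class ROCResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


def roc_auc(scores, labels) -> ROCResult:
    """AUC with DeLong variance and a 95% normal CI clipped to [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _placements(s, y)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(var)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    thr = np.unique(s)[::-1]
    sens = np.empty(len(thr))
    spec = np.empty(len(thr))
    for i, t in enumerate(thr):
        pred = s >= t
        sens[i] = (pred & (y == 1)).sum() / m
        spec[i] = (~pred & (y == 0)).sum() / n
    return ROCResult(auc, float(var), ci, thr, sens, spec, s, y)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for two correlated AUCs on the same patients.

    Returns (z, two-sided p).  Raises when the variance of the AUC
    difference is degenerate (e.g. identical score vectors).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired scores and labels must share a shape")
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if np.array_equal(sa, sb):
        raise ValueError("degenerate variance: the two score vectors are identical")
    if var_diff <= 1e-15:
        # rank-preserving transforms give identical placements: the AUC
        # difference is exactly 0 with no variance left to test against
        if auc_a == auc_b:
            return 0.0, 1.0
        raise ValueError("degenerate variance of the AUC difference "
                         "(are both models perfect separators?)")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "PPV": self.ppv, "NPV": self.npv, "accuracy": self.accuracy,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Exact-ratio confusion metrics; zero denominators yield NaN flags."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ValueError("empty confusion matrix")
    return ConfusionMetrics(tp, fp, tn, fn)


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionMetrics:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = s >= cutoff
    return ConfusionMetrics(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


@dataclass
class CutoffResult:
    cutoff: float
    youden_j: float
    metrics: ConfusionMetrics


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity − 1 over observed
    thresholds; ties prefer higher sensitivity, then the lower cutoff."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = 0
    for i in range(1, len(j)):
        if (j[i], roc.sensitivity[i], -roc.thresholds[i]) > (
            j[best], roc.sensitivity[best], -roc.thresholds[best]
        ):
            best = i
    cut = float(roc.thresholds[best])
    return CutoffResult(cut, float(j[best]), confusion_at_cutoff(roc.scores, roc.labels, cut))


@dataclass
class CalibrationResult:
    bins: np.ndarray  # (mean predicted, observed rate, count) per group
    hl_statistic: float
    hl_p: float
    df: int


def hosmer_lemeshow(probs, labels, groups: int = 10) -> CalibrationResult:
    """Hosmer–Lemeshow χ² over equal-count probability deciles.

    Ties are assigned to the lower bin; groups whose expected event count
    is zero are merged with their neighbour.  The statistic
    ``Σ (O − E)² / (E (1 − E/n_g))`` is referred to χ² with g − 2 degrees
    of freedom.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(p)
    if n < 2 * groups:
        raise ValueError("need at least 2 observations per group")
    order = np.argsort(p, kind="stable")
    # equal-count bins over the sorted order; ties to the lower bin
    edges = [int(round(g * n / groups)) for g in range(groups + 1)]
    bin_of = np.empty(n, dtype=int)
    sorted_p = p[order]
    for g in range(groups):
        bin_of[order[edges[g]:edges[g + 1]]] = g
    # push ties across an edge down into the lower bin
    for g in range(1, groups):
        if edges[g] == 0 or edges[g] >= n:
            continue
        boundary = sorted_p[edges[g] - 1]
        tied = order[edges[g]:][sorted_p[edges[g]:] == boundary]
        bin_of[tied] = np.minimum(bin_of[tied], g - 1)
    rows = []
    for g in range(groups):
        sel = bin_of == g
        if not sel.any():
            continue
        rows.append([p[sel].sum(), y[sel].sum(), int(sel.sum()), p[sel].mean()])
    # merge groups with zero expected events into the neighbour above
    merged = []
    for row in rows:
        if merged and (row[0] <= 0 or merged[-1][0] <= 0):
            merged[-1] = [a + b for a, b in zip(merged[-1][:3], row[:3])] + [0.0]
            merged[-1][3] = merged[-1][0] / merged[-1][2]
        else:
            merged.append(list(row))
    hl = 0.0
    bins = []
    for e, o, ng, meanp in merged:
        denom = e * (1.0 - e / ng)
        if denom <= 0:
            continue
        hl += (o - e) ** 2 / denom
        bins.append((meanp, o / ng, ng))
    df = max(len(merged) - 2, 1)
    pval = float(stats.chi2.sf(hl, df))
    return CalibrationResult(np.array(bins), float(hl), pval, df)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


def decision_curve(probs, labels, thresholds=None) -> NetBenefitCurve:
    """Decision-curve net benefit ``TP/n − FP/n · pt/(1 − pt)``.

    ``positive ⇔ prob ≥ pt``.  Includes treat-all (prevalence −
    (1 − prevalence)·pt/(1 − pt)) and treat-none (identically 0)
    references.  Thresholds at or above 1 are excluded.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    pt = np.asarray(thresholds, dtype=float)
    pt = pt[(pt > 0) & (pt < 1)]
    n = len(y)
    prev = y.mean()
    nb = np.empty(len(pt))
    for i, t in enumerate(pt):
        pred = p >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * t / (1.0 - t)
    treat_all = prev - (1.0 - prev) * pt / (1.0 - pt)
    return NetBenefitCurve(pt, nb, treat_all, np.zeros(len(pt)))


def two_by_two_tests(table) -> dict[str, float]:
    """Pearson χ² (no continuity correction, df 1), Fisher exact (two-sided)
    and the cross-product odds ratio ad/bc for a 2×2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2×2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in the 2×2 table")
    chi2 = stats.chi2_contingency(t, correction=False)
    fisher = stats.fisher_exact(t)
    a, b, c, d = t.ravel()
    orr = (a * d) / (b * c) if b * c > 0 else float("inf")
    return {
        "chi2": float(chi2.statistic),
        "chi2_p": float(chi2.pvalue),
        "fisher_p": float(fisher.pvalue),
        "odds_ratio": float(orr),
    }
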