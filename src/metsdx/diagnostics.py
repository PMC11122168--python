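"""Diagnostic-accuracy statistics: ROC curves, AUC with confidence intervals,
Youden-index cutoffs, likelihood ratios, and the supporting comparison tests.

Conventions
-----------
* A subject is test-positive when its score is **>= threshold**; candidate
  thresholds are the distinct observed scores plus +/- infinity sentinels.
  Higher score means predicted disease: the analysis never auto-flips the
  direction.
* Sensitivity and specificity are carried in percent throughout, matching
  how screening studies report them; Youden's J = sens/100 + spec/100 - 1.
* The AUC is computed as the Mann-Whitney probability (ties credited 1/2),
  which is algebraically identical to the trapezoidal area under the
  empirical ROC curve.
* The default AUC confidence interval is DeLong's nonparametric estimator
  (deterministic); a seeded stratified bootstrap is available as a
  cross-check.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: |r| bands for qualitative correlation strength.
STRENGTH_BANDS = (
    (0.10, "negligible"),
    (0.40, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (float("inf"), "very strong"),
)

P_BINS = ((0.0001, "<0.0001"), (0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"))


@dataclass
class ROCResult:
    """A complete single-curve ROC analysis.

    ``points`` is an (k, 3) array of (threshold, sensitivity %, specificity %)
    ordered by descending threshold; the operating point is the Youden-optimal
    cutoff.
    """

    points: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    youden_j: float
    lr_pos: float
    lr_neg: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    strength: str


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("labels are degenerate: need at least one positive "
                         "and one negative")
    return scores, labels


def roc_points(scores, labels) -> np.ndarray:
    """Empirical ROC operating points.

    Returns an array of (threshold, sensitivity %, specificity %) rows, one
    per candidate threshold (distinct observed scores plus +inf and -inf
    sentinels), ordered by descending threshold.  Test-positive means
    score >= threshold.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # last occurrence of each distinct score in the descending sort
    last = np.nonzero(np.append(s[1:] != s[:-1], True))[0]
    thresholds = np.concatenate(([np.inf], s[last], [-np.inf]))
    sens = np.concatenate(([0.0], tp[last], [float(n_pos)])) / n_pos * 100.0
    spec = 100.0 - np.concatenate(([0.0], fp[last], [float(n_neg)])) / n_neg * 100.0
    return np.column_stack([thresholds, sens, spec])


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney probability.

    Equals (pairs with positive score > negative score + half the ties) over
    all (positive, negative) pairs, and equals the trapezoidal area under
    :func:`roc_points`.
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def trapezoid_auc(points: np.ndarray) -> float:
    """AUC by trapezoidal integration of ROC points (cross-check route)."""
    fpr = 1.0 - points[:, 2] / 100.0
    tpr = points[:, 1] / 100.0
    return float(np.trapezoid(tpr, fpr))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong's AUC estimate and its variance via placement values."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    # placement of each positive among negatives (and vice versa), ties 1/2
    order = np.argsort(neg, kind="mergesort")
    neg_sorted = neg[order]
    v10 = (np.searchsorted(neg_sorted, pos, side="left")
           + np.searchsorted(neg_sorted, pos, side="right")) / (2.0 * n)
    pos_sorted = np.sort(pos, kind="mergesort")
    v01 = 1.0 - (np.searchsorted(pos_sorted, neg, side="left")
                 + np.searchsorted(pos_sorted, neg, side="right")) / (2.0 * m)
    theta = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return theta, s10 / m + s01 / n


def auc_confidence_interval(scores, labels, level: float = 0.95,
                            method: str = "delong", n_boot: int = 2000,
                            seed: int | None = None) -> tuple[float, float]:
    """Two-sided AUC confidence interval, clamped to [0, 1].

    ``method='delong'`` (default) uses DeLong's nonparametric variance
    estimator and a normal quantile; ``method='bootstrap'`` uses a seeded
    stratified percentile bootstrap.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if int(labels.sum()) < 2 or int((~labels).sum()) < 2:
        raise ValueError("need at least 2 subjects in each class for a CI")
    if method == "delong":
        theta, var = _delong_variance(scores, labels)
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(max(var, 0.0))
        return max(0.0, theta - half), min(1.0, theta + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bs = np.concatenate([bp, bn])
            bl = np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)])
            reps[b] = auc(bs, bl)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
        return float(max(0.0, lo)), float(min(1.0, hi))
    raise ValueError(f"unknown CI method {method!r}")


def youden_cutoff(points: np.ndarray) -> tuple[float, float, float, float]:
    """The threshold maximizing Youden's J over all candidate thresholds.

    Returns (cutoff, sensitivity %, specificity %, J).  Ties in J are broken
    by the higher specificity (a screening test should minimize false
    positives), then by the higher threshold.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty ROC points")
    j = points[:, 1] / 100.0 + points[:, 2] / 100.0 - 1.0
    best = 0
    for i in range(1, len(points)):
        key = (j[i], points[i, 2], points[i, 0])
        if key > (j[best], points[best, 2], points[best, 0]):
            best = i
    return (float(points[best, 0]), float(points[best, 1]),
            float(points[best, 2]), float(j[best]))


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Positive and negative likelihood ratios from percent sens/spec.

    LR+ = sens / (100 - spec); LR- = (100 - sens) / spec.  A zero
    denominator yields +inf (or NaN for the indeterminate 0/0 case).
    """
    if not (0.0 <= sensitivity <= 100.0 and 0.0 <= specificity <= 100.0):
        raise ValueError("sensitivity and specificity must be in [0, 100]")
    if specificity >= 100.0:
        lr_pos = math.inf if sensitivity > 0 else math.nan
    else:
        lr_pos = sensitivity / (100.0 - specificity)
    if specificity <= 0.0:
        lr_neg = math.inf if sensitivity < 100.0 else math.nan
    else:
        lr_neg = (100.0 - sensitivity) / specificity
    return lr_pos, lr_neg


def roc_analyze(scores, labels, level: float = 0.95, ci_method: str = "delong",
                n_boot: int = 2000, seed: int | None = None) -> ROCResult:
    """Full single-curve analysis: points, AUC + CI, Youden cutoff, LRs."""
    scores, labels = _check_scores_labels(scores, labels)
    points = roc_points(scores, labels)
    area = auc(scores, labels)
    lo, hi = auc_confidence_interval(scores, labels, level=level,
                                     method=ci_method, n_boot=n_boot, seed=seed)
    cutoff, sens, spec, j = youden_cutoff(points)
    lr_pos, lr_neg = likelihood_ratios(sens, spec)
    return ROCResult(points=points, auc=area, ci_low=lo, ci_high=hi,
                     cutoff=cutoff, sensitivity_at_cutoff=sens,
                     specificity_at_cutoff=spec, youden_j=j,
                     lr_pos=lr_pos, lr_neg=lr_neg,
                     n_pos=int(labels.sum()), n_neg=int((~labels).sum()))


def unpaired_t_test(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test (pooled variance by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 table of counts.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's.  The
    comparison is done in exact integer arithmetic, so the result agrees with
    full enumeration with no floating-point tie ambiguity.
    """
    arr = np.asarray(table, dtype=object)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        raise ValueError("all margins must be positive")
    observed = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        term = math.comb(r1, k) * math.comb(r2, c1 - k)
        if term <= observed:
            total += term
    return total / math.comb(n, c1)


def strength_of(r: float) -> str:
    """Qualitative band for a correlation coefficient's magnitude."""
    magnitude = abs(r)
    for upper, label in STRENGTH_BANDS:
        if magnitude < upper:
            return label
    return "very strong"  # pragma: no cover - inf band always matches


def pearson_with_strength(x, y) -> CorrelationResult:
    """Pearson correlation with r^2, two-sided p, and a strength band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    return CorrelationResult(r=r, r_squared=r * r, p_value=float(p),
                             strength=strength_of(r))


def p_bin(p: float) -> str:
    """Bin a p-value the way clinical tables print significance."""
    if math.isnan(p):
        return "ns"
    for cut, label in P_BINS:
        if p < cut:
            return label
    return "ns"
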