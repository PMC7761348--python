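"""Reader-agreement and diagnostic-accuracy statistics for joint uptake data.

Implements the evaluation battery applied to whole-body joint uptake ratios
and two-reader ordinal grades:

* weighted Cohen's kappa (linear or quadratic weights) with the
  Fleiss-Cohen-Everitt large-sample confidence interval, plus exact
  percent agreement;
* Lin's concordance correlation coefficient (CCC) with the Fisher-z interval;
* ROC analysis via the Mann-Whitney identity (AUC = probability a random
  positive outscores a random negative, ties counted half), with DeLong
  variance for confidence intervals and the DeLong paired test for comparing
  two correlated AUCs; Bonferroni thresholds for families of comparisons;
* Youden-optimal cutoffs and full diagnostic performance (sensitivity,
  specificity, PPV, NPV, accuracy) with exact Clopper-Pearson binomial
  confidence intervals;
* group comparison by Welch's t-test or the Mann-Whitney test.

Conventions fixed here so tabulated outputs are reproducible: positivity is
"score > cutoff"; Youden ties break to the lowest cutoff; percentages round
half-away-from-zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "RocResult",
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticPerformance",
    "StatsError",
    "LengthMismatchError",
    "DegenerateDataError",
    "SingleClassError",
    "weighted_kappa",
    "exact_agreement",
    "ccc",
    "auc_mann_whitney",
    "delong_paired_test",
    "bonferroni_threshold",
    "youden_optimal_cutoff",
    "diagnostic_performance",
    "counts_from_summary",
    "compare_groups",
    "clopper_pearson",
    "round_half_away",
]

GRADES = (1, 2, 3)


class StatsError(ValueError):
    pass


class LengthMismatchError(StatsError):
    pass


class DegenerateDataError(StatsError):
    pass


class SingleClassError(DegenerateDataError):
    """Raised when a ROC-type analysis receives only one class."""


@dataclass(frozen=True)
class AgreementResult:
    statistic: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    thresholds: np.ndarray  # candidate cutoffs, descending
    sensitivity: np.ndarray  # P(score > cutoff | positive), per threshold
    specificity: np.ndarray  # P(score <= cutoff | negative), per threshold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise StatsError("confusion counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage with its exact binomial 95% CI; None when undefined."""

    value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @classmethod
    def undefined(cls) -> "MetricEstimate":
        return cls(None, None, None)


@dataclass(frozen=True)
class DiagnosticPerformance:
    cutoff: Optional[float]
    counts: ConfusionCounts
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# agreement


def _as_grade_arrays(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise LengthMismatchError("grade vectors must be 1-D and of equal length")
    for v in (a, b):
        if not np.isin(v, GRADES).all():
            raise StatsError(f"grades must be in {set(GRADES)}")
    return a.astype(int), b.astype(int)


def _weight_matrix(kind: str, k: int) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if kind == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if kind == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    raise StatsError(f"weights must be 'linear' or 'quadratic', got {kind!r}")


def weighted_kappa(
    grades_a, grades_b, weights: str = "linear", alpha: float = 0.05
) -> AgreementResult:
    """Weighted Cohen's kappa for two raters' ordinal 1-3 grades.

    kappa_w = (p_o - p_e) / (1 - p_e) with agreement weights w_ij
    (1 - |i-j|/(k-1) linear, 1 - ((i-j)/(k-1))^2 quadratic), p_o the weighted
    observed and p_e the weighted chance-expected agreement from the
    marginals; equivalently 1 - sum(v O)/sum(v E) with disagreement weights
    v = 1 - w.  The CI uses the Fleiss-Cohen-Everitt large-sample variance.
    """
    a, b = _as_grade_arrays(grades_a, grades_b)
    n = len(a)
    if n < 2:
        raise StatsError("weighted kappa requires at least 2 paired grades")
    k = len(GRADES)
    table = np.zeros((k, k))
    for ga, gb in zip(a, b):
        table[ga - 1, gb - 1] += 1
    p = table / n
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    w = _weight_matrix(weights, k)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(pi, pj)).sum())
    if 1.0 - p_e <= 1e-15:
        raise DegenerateDataError(
            "chance-expected weighted agreement is 1 (no variation in the raters); "
            "kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    w_i = w @ pj  # row-weight averages
    w_j = w.T @ pi
    term = (w - np.add.outer(w_i, w_j) * (1.0 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - p_e * (1.0 - kappa)) ** 2) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(1 - alpha / 2)
    return AgreementResult(
        statistic=float(kappa),
        ci_low=max(-1.0, kappa - z * se),
        ci_high=min(1.0, kappa + z * se),
        n=n,
    )


def exact_agreement(grades_a, grades_b) -> float:
    """Percent of joints on which the two readers give the identical grade."""
    a = np.asarray(grades_a)
    b = np.asarray(grades_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise LengthMismatchError("grade vectors must be 1-D, non-empty, equal length")
    return 100.0 * float(np.mean(a == b))


def ccc(x, y, alpha: float = 0.05) -> AgreementResult:
    """Lin's concordance correlation coefficient for paired measurements.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with biased (1/n)
    moment estimators; the CI back-transforms a normal interval on
    z = atanh(CCC) using Lin's variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthMismatchError("paired vectors must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise StatsError("CCC requires at least 3 pairs")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom <= 0:
        raise DegenerateDataError("both vectors are constant and equal; CCC undefined")
    rho_c = 2.0 * sxy / denom

    if sx2 <= 0 or sy2 <= 0:
        # one constant vector: CCC is 0 with no usable large-sample variance
        return AgreementResult(float(rho_c), float("nan"), float("nan"), n)

    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    one_m = max(1.0 - rho_c**2, 1e-15)
    if abs(r) < 1e-15:
        se_z = float("nan")
    else:
        var_z = (
            (1.0 - r**2) * rho_c**2 / (one_m * r**2)
            + 2.0 * rho_c**3 * (1.0 - rho_c) * u**2 / (r * one_m**2)
            - rho_c**4 * u**4 / (2.0 * r**2 * one_m**2)
        ) / (n - 2)
        se_z = math.sqrt(max(var_z, 0.0))
    if not math.isfinite(se_z):
        return AgreementResult(float(rho_c), float("nan"), float("nan"), n)
    zq = sps.norm.ppf(1 - alpha / 2)
    zc = math.atanh(max(min(rho_c, 1 - 1e-12), -1 + 1e-12))
    return AgreementResult(
        statistic=float(rho_c),
        ci_low=math.tanh(zc - zq * se_z),
        ci_high=math.tanh(zc + zq * se_z),
        n=n,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise LengthMismatchError("scores and labels must be 1-D and of equal length")
    lab = labels.astype(bool) if labels.dtype != bool else labels
    pos = scores[lab]
    neg = scores[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("ROC analysis requires both classes to be present")
    return pos, neg


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values V10 (per positive), V01 (per negative)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    tz = _midrank(allv)
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def auc_mann_whitney(scores, labels, alpha: float = 0.05) -> RocResult:
    """AUC by the Mann-Whitney pair-counting identity, CI by DeLong variance.

    AUC = (wins + 0.5 * ties) / (n_pos * n_neg) over all positive-negative
    score pairs.  The threshold table reports sensitivity/specificity of the
    rule "score > cutoff => positive" at every distinct observed score.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    auc, v10, v01 = _placements(pos, neg)
    var = _delong_var_single(v10, v01)
    se = math.sqrt(max(var, 0.0))
    z = sps.norm.ppf(1 - alpha / 2)

    cutoffs = np.unique(np.concatenate([pos, neg]))[::-1]
    sens = np.array([(pos > c).mean() for c in cutoffs])
    spec = np.array([(neg <= c).mean() for c in cutoffs])
    return RocResult(
        auc=float(auc),
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        n_pos=m,
        n_neg=n,
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
    )


def _delong_var_single(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_paired_test(scores_1, scores_2, labels) -> tuple[float, float, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors rank the same subjects.  Returns
    (auc_1 - auc_2, z, two-sided p) using the placement-value covariance.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if s1.shape != s2.shape:
        raise LengthMismatchError("paired score vectors must have equal length")
    pos1, neg1 = _split_scores(s1, labels)
    pos2, neg2 = _split_scores(s2, labels)
    auc1, v10_1, v01_1 = _placements(pos1, neg1)
    auc2, v10_2, v01_2 = _placements(pos2, neg2)
    m, n = len(pos1), len(neg1)

    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    delta = auc1 - auc2
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-16:
        # identical placement structure: no evidence against equality unless
        # the point estimates differ, which a zero-variance pair cannot
        return float(delta), 0.0, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return float(delta), float(z), min(p, 1.0)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Per-comparison significance threshold alpha / k."""
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must lie in (0, 1)")
    if k < 1:
        raise StatsError("number of comparisons must be >= 1")
    return alpha / k


# ---------------------------------------------------------------------------
# diagnostic performance


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial 95% CI bounds (as percentages) for k successes of n."""
    if not 0 <= k <= n or n < 1:
        raise StatsError("require 0 <= k <= n and n >= 1")
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * lo, 100.0 * hi


def _metric(k: int, n: int, alpha: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate.undefined()
    lo, hi = clopper_pearson(k, n, alpha)
    return MetricEstimate(100.0 * k / n, lo, hi)


def diagnostic_performance(
    counts: ConfusionCounts, cutoff: Optional[float] = None, alpha: float = 0.05
) -> DiagnosticPerformance:
    """Sensitivity/specificity/PPV/NPV/accuracy (percent) with exact CIs.

    Each metric gets a Clopper-Pearson interval on its own numerator and
    denominator; a metric with an empty denominator (e.g. PPV with no test
    positives) is reported as undefined, never as zero.
    """
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise SingleClassError("diagnostic performance requires positives and negatives")
    return DiagnosticPerformance(
        cutoff=cutoff,
        counts=counts,
        sensitivity=_metric(counts.tp, counts.n_pos, alpha),
        specificity=_metric(counts.tn, counts.n_neg, alpha),
        ppv=_metric(counts.tp, counts.tp + counts.fp, alpha),
        npv=_metric(counts.tn, counts.tn + counts.fn, alpha),
        accuracy=_metric(counts.tp + counts.tn, counts.total, alpha),
    )


def youden_optimal_cutoff(scores, labels, alpha: float = 0.05) -> DiagnosticPerformance:
    """Diagnostic performance at the cutoff maximising Youden's J.

    J = sensitivity + specificity - 1 is scanned over all observed score
    values under the rule "score > cutoff => positive"; ties break to the
    lowest cutoff.
    """
    pos, neg = _split_scores(scores, labels)
    roc = auc_mann_whitney(scores, labels, alpha)
    j = roc.sensitivity + roc.specificity - 1.0
    # thresholds are descending; among argmax ties pick the lowest cutoff
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]
    cutoff = float(roc.thresholds[best])
    tp = int((pos > cutoff).sum())
    tn = int((neg <= cutoff).sum())
    counts = ConfusionCounts(tp=tp, fp=len(neg) - tn, tn=tn, fn=len(pos) - tp)
    return diagnostic_performance(counts, cutoff=cutoff, alpha=alpha)


def counts_from_summary(
    sens_pct: float, spec_pct: float, n_pos: int, n_neg: int
) -> list[ConfusionCounts]:
    """All integer confusion counts consistent with one-decimal percentages.

    Inverts table rounding: returns every (tp, tn) whose sensitivity and
    specificity round (half away from zero, one decimal) to the printed
    values.  May be empty if the printed pair is inconsistent.
    """
    if not (0.0 <= sens_pct <= 100.0 and 0.0 <= spec_pct <= 100.0):
        raise StatsError("percentages must lie in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise StatsError("group sizes must be >= 1")
    tps = [
        tp for tp in range(n_pos + 1) if round_half_away(100.0 * tp / n_pos, 1) == sens_pct
    ]
    tns = [
        tn for tn in range(n_neg + 1) if round_half_away(100.0 * tn / n_neg, 1) == spec_pct
    ]
    return [
        ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
        for tp in tps
        for tn in tns
    ]


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(x, y, method: str = "mann-whitney") -> float:
    """Two-sided p for a difference between independent samples.

    't-test' is Welch's unequal-variance form; 'mann-whitney' uses exact
    enumeration for small tie-free samples (both n <= 20) and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("each group needs at least 2 observations")
    if method == "t-test":
        return float(sps.ttest_ind(x, y, equal_var=False).pvalue)
    if method == "mann-whitney":
        pooled = np.concatenate([x, y])
        if len(np.unique(pooled)) == 1:
            return 1.0  # every observation tied: no evidence either way
        has_ties = len(np.unique(pooled)) < len(pooled)
        small = max(len(x), len(y)) <= 20
        mw_method = "exact" if (small and not has_ties) else "asymptotic"
        return float(
            sps.mannwhitneyu(x, y, alternative="two-sided", method=mw_method).pvalue
        )
    raise StatsError(f"method must be 't-test' or 'mann-whitney', got {method!r}")
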