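"""Agreement and diagnostic-accuracy statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from scintiquant.diagstats import (
    ConfusionCounts,
    DegenerateDataError,
    LengthMismatchError,
    SingleClassError,
    StatsError,
    auc_mann_whitney,
    bonferroni_threshold,
    ccc,
    clopper_pearson,
    compare_groups,
    counts_from_summary,
    delong_paired_test,
    diagnostic_performance,
    exact_agreement,
    round_half_away,
    weighted_kappa,
    youden_optimal_cutoff,
)

# ---------------------------------------------------------------------------
# independent oracles


def kappa_oracle(a, b, weights="linear"):
    """Brute-force weighted kappa: explicit cell-by-cell disagreement sums."""
    n = len(a)
    k = 3
    O = [[0.0] * k for _ in range(k)]
    for ga, gb in zip(a, b):
        O[ga - 1][gb - 1] += 1.0 / n
    pi = [sum(O[i][j] for j in range(k)) for i in range(k)]
    pj = [sum(O[i][j] for i in range(k)) for j in range(k)]
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            v = abs(i - j) / (k - 1) if weights == "linear" else ((i - j) / (k - 1)) ** 2
            num += v * O[i][j]
            den += v * pi[i] * pj[j]
    return 1.0 - num / den


def auc_oracle(scores, labels):
    """Exhaustive positive-negative pair counting, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def mannwhitney_oracle(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# weighted kappa


class TestWeightedKappa:
    def test_identical_raters(self):
        g = np.array([1, 2, 3, 1, 2, 3, 2])
        assert weighted_kappa(g, g).statistic == pytest.approx(1.0)

    def test_printed_contingency_table(self):
        # rows (5,1,0 / 1,5,1 / 0,1,6) unrolled to paired grade vectors
        table = [(5, 1, 1), (1, 1, 2), (0, 1, 3), (1, 2, 1), (5, 2, 2), (1, 2, 3),
                 (0, 3, 1), (1, 3, 2), (6, 3, 3)]
        a, b = [], []
        for count, ga, gb in table:
            a += [ga] * count
            b += [gb] * count
        for weights in ("linear", "quadratic"):
            res = weighted_kappa(a, b, weights=weights)
            assert res.statistic == pytest.approx(kappa_oracle(a, b, weights), abs=1e-12)
            assert res.ci_low <= res.statistic <= res.ci_high

    @given(
        a=st.lists(st.integers(1, 3), min_size=4, max_size=60),
        b=st.lists(st.integers(1, 3), min_size=4, max_size=60),
    )
    def test_matches_bruteforce_oracle(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if len(set(a)) == 1 and len(set(b)) == 1:
            return  # degenerate: kappa undefined
        for weights in ("linear", "quadratic"):
            res = weighted_kappa(a, b, weights=weights)
            assert res.statistic == pytest.approx(kappa_oracle(a, b, weights), abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(1, 4, 500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(1, 4, 500))
        for ours, theirs in (("linear", "linear"), ("quadratic", "quadratic")):
            res = weighted_kappa(a, b, weights=ours)
            assert res.statistic == pytest.approx(
                cohen_kappa_score(a, b, weights=theirs), abs=1e-12
            )

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(1, 4, 100_000)
        b = rng.integers(1, 4, 100_000)
        assert abs(weighted_kappa(a, b).statistic) < 0.02

    def test_invariant_to_joint_permutation(self, rng):
        a = rng.integers(1, 4, 200)
        b = rng.integers(1, 4, 200)
        perm = rng.permutation(200)
        assert weighted_kappa(a, b).statistic == pytest.approx(
            weighted_kappa(a[perm], b[perm]).statistic
        )

    def test_errors(self):
        with pytest.raises(LengthMismatchError):
            weighted_kappa([1, 2], [1, 2, 3])
        with pytest.raises(StatsError):
            weighted_kappa([1, 4], [1, 2])
        with pytest.raises(DegenerateDataError):
            weighted_kappa([2, 2, 2], [2, 2, 2])


class TestExactAgreement:
    def test_identical(self):
        assert exact_agreement([1, 2, 3], [1, 2, 3]) == 100.0

    def test_study_scale_bookkeeping(self):
        # 4844 concordant grade pairs among 5941 joints -> 81.5%
        a = np.ones(5941, dtype=int)
        b = np.ones(5941, dtype=int)
        b[4844:] = 2
        assert round_half_away(exact_agreement(a, b), 1) == 81.5

    def test_fully_discordant(self):
        assert exact_agreement([1, 2, 1], [2, 1, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            exact_agreement([1], [1, 2])


# ---------------------------------------------------------------------------
# CCC


class TestCcc:
    def test_identity(self, rng):
        x = rng.normal(0, 1, 50)
        res = ccc(x, x.copy())
        assert res.statistic == pytest.approx(1.0)
        assert res.ci_high <= 1.0

    def test_constant_shift_closed_form(self, rng):
        x = rng.normal(0, 1.3, 400)
        c = 0.7
        res = ccc(x, x + c)
        s2 = np.mean((x - x.mean()) ** 2)
        assert res.statistic == pytest.approx(2 * s2 / (2 * s2 + c**2), rel=1e-12)

    def test_perfect_reversal(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ccc(x, -x).statistic == pytest.approx(-1.0)

    def test_ci_brackets_statistic(self, rng):
        x = rng.normal(0, 1, 100)
        y = x + rng.normal(0, 0.3, 100)
        res = ccc(x, y)
        assert res.ci_low <= res.statistic <= res.ci_high

    def test_errors(self):
        with pytest.raises(StatsError):
            ccc([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            ccc([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# AUC / DeLong


class TestAuc:
    def test_perfect_separation(self):
        res = auc_mann_whitney([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_all_ties(self):
        res = auc_mann_whitney([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert res.auc == 0.5

    def test_small_examples(self):
        assert auc_mann_whitney([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(0, 1, 300)
        labels = rng.random(300) < 0.3
        labels[0], labels[1] = True, False
        res = auc_mann_whitney(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(
        scores=st.lists(st.integers(0, 6), min_size=4, max_size=30),
        data=st.data(),
    )
    def test_matches_pair_counting_oracle(self, scores, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(scores), max_size=len(scores))
        )
        if not (any(labels) and not all(labels)):
            return
        res = auc_mann_whitney(np.array(scores, dtype=float), np.array(labels))
        assert res.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-12)

    def test_ci_brackets_auc(self, rng):
        scores = rng.normal(0, 1, 100) + rng.random(100)
        labels = rng.random(100) < 0.4
        labels[:2] = [True, False]
        res = auc_mann_whitney(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc_mann_whitney([1.0, 2.0], [1, 1])


class TestDelong:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.normal(0, 1, 40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        delta, z, p = delong_paired_test(s, s.copy(), labels)
        assert delta == 0.0 and p == 1.0

    def test_power_under_strong_separation(self, rng):
        labels = np.repeat([True, False], 100)
        informative = labels + rng.normal(0, 0.3, 200)
        noise = rng.normal(0, 1, 200)
        _, _, p = delong_paired_test(informative, noise, labels)
        assert p < 0.05

    def test_symmetry(self, rng):
        labels = np.repeat([True, False], 30)
        s1 = labels + rng.normal(0, 1, 60)
        s2 = labels + rng.normal(0, 2, 60)
        d12, z12, p12 = delong_paired_test(s1, s2, labels)
        d21, z21, p21 = delong_paired_test(s2, s1, labels)
        assert d12 == pytest.approx(-d21)
        assert p12 == pytest.approx(p21)

    def test_close_to_permutation_oracle_small_n(self, rng):
        """Sign-flip permutation of the paired scores as a reference null."""
        for trial in range(4):
            labels = np.array([True] * 5 + [False] * 7)
            s1 = labels + rng.normal(0, 1.0, 12)
            s2 = labels + rng.normal(0, 1.5, 12)
            _, _, p = delong_paired_test(s1, s2, labels)
            obs = abs(
                auc_mann_whitney(s1, labels).auc - auc_mann_whitney(s2, labels).auc
            )
            hits = 0
            n_perm = 600
            for _ in range(n_perm):
                flip = rng.random(12) < 0.5
                a = np.where(flip, s2, s1)
                b = np.where(flip, s1, s2)
                d = abs(
                    auc_mann_whitney(a, labels).auc - auc_mann_whitney(b, labels).auc
                )
                hits += d >= obs - 1e-12
            p_perm = hits / n_perm
            assert abs(p - p_perm) < 0.25

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            delong_paired_test([1.0, 2.0], [1.0], [True, False])


# ---------------------------------------------------------------------------
# cutoffs and diagnostic performance


class TestBonferroni:
    def test_three_comparisons(self):
        t = bonferroni_threshold(0.05, 3)
        assert t == pytest.approx(1 / 60)
        assert round_half_away(t, 3) == 0.017

    @pytest.mark.parametrize("alpha,k,expected", [(0.05, 1, 0.05), (0.06, 2, 0.03)])
    def test_simple_cases(self, alpha, k, expected):
        assert bonferroni_threshold(alpha, k) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(StatsError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(StatsError):
            bonferroni_threshold(1.2, 3)


class TestYouden:
    def test_perfect_separation_with_gap(self):
        perf = youden_optimal_cutoff([0.5, 1.0, 1.5, 2.0], [0, 0, 1, 1])
        assert 1.0 <= perf.cutoff < 1.5
        assert perf.sensitivity.value == 100.0
        assert perf.specificity.value == 100.0

    def test_exhaustive_threshold_scan(self, rng):
        scores = rng.normal(0, 1, 40) + rng.random(40)
        labels = rng.random(40) < 0.4
        labels[:2] = [True, False]
        perf = youden_optimal_cutoff(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        best = max(
            (pos > c).mean() + (neg <= c).mean() - 1.0 for c in np.unique(scores)
        )
        got = perf.sensitivity.value / 100 + perf.specificity.value / 100 - 1.0
        assert got == pytest.approx(best, abs=1e-12)

    def test_tie_breaks_to_lowest_cutoff(self):
        # cutoffs 1.0 and 2.0 both give J = 0.5; the lower must win
        scores = [1.0, 2.0, 3.0, 0.0]
        labels = [0, 1, 1, 0]
        perf = youden_optimal_cutoff(scores, labels)
        assert perf.cutoff == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            youden_optimal_cutoff([1.0, 2.0], [1, 1])


class TestDiagnosticPerformance:
    def test_sacroiliac_style_counts(self):
        perf = diagnostic_performance(ConfusionCounts(tp=4, fp=70, tn=112, fn=0))
        assert round_half_away(perf.sensitivity.value, 1) == 100.0
        assert round_half_away(perf.specificity.value, 1) == 61.5
        assert round_half_away(perf.ppv.value, 1) == 5.4
        assert round_half_away(perf.npv.value, 1) == 100.0
        assert round_half_away(perf.accuracy.value, 1) == 62.4
        # exact binomial lower bound for 4/4: 0.025**(1/4)
        assert perf.sensitivity.ci_low == pytest.approx(100 * 0.025 ** 0.25, abs=1e-9)
        assert round_half_away(perf.sensitivity.ci_low, 1) == 39.8

    def test_accuracy_identity_and_bayes(self, rng):
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            counts = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            perf = diagnostic_performance(counts)
            total = counts.total
            assert perf.accuracy.value * total / 100 == pytest.approx(tp + tn)
            if perf.ppv.value is not None:
                sens = perf.sensitivity.value / 100
                spec = perf.specificity.value / 100
                prev = counts.n_pos / total
                bayes = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
                assert perf.ppv.value / 100 == pytest.approx(bayes)

    def test_undefined_metric_flagged_not_zero(self):
        perf = diagnostic_performance(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert perf.ppv.value is None

    def test_empty_class_rejected(self):
        with pytest.raises(SingleClassError):
            diagnostic_performance(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))

    def test_clopper_pearson_edges(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and hi == pytest.approx(100 * (1 - 0.025 ** 0.1))


class TestCountsFromSummary:
    def test_unique_solution(self):
        sols = counts_from_summary(100.0, 61.5, 4, 182)
        assert sols == [ConfusionCounts(tp=4, fp=70, tn=112, fn=0)]

    def test_contiguous_set_total_row(self):
        sols = counts_from_summary(75.1, 70.7, 728, 5213)
        tps = sorted({s.tp for s in sols})
        tns = sorted({s.tn for s in sols})
        assert tps == [547]
        assert tns == list(range(tns[0], tns[-1] + 1))  # small contiguous set
        assert len(tns) <= 8

    def test_tiny_case(self):
        sols = counts_from_summary(50.0, 50.0, 2, 2)
        assert sols == [ConfusionCounts(tp=1, fp=1, tn=1, fn=1)]

    def test_inconsistent_pair_gives_empty_set(self):
        assert counts_from_summary(33.0, 50.0, 2, 2) == []


# ---------------------------------------------------------------------------
# group comparison


class TestCompareGroups:
    def test_all_ties_mann_whitney(self):
        assert compare_groups([1.0, 1.0, 1.0], [1.0, 1.0], method="mann-whitney") == 1.0

    def test_strong_separation(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        assert compare_groups(x, y, method="t-test") < 0.001
        assert compare_groups(x, y, method="mann-whitney") < 0.001

    def test_exact_mw_matches_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.8, 1, 7)
            p = compare_groups(x, y, method="mann-whitney")
            assert p == pytest.approx(mannwhitney_oracle(x, y), abs=1e-9)

    def test_welch_matches_scipy(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 2, 40)
        assert compare_groups(x, y, method="t-test") == pytest.approx(
            sps.ttest_ind(x, y, equal_var=False).pvalue
        )

    def test_errors(self):
        with pytest.raises(StatsError):
            compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(StatsError):
            compare_groups([1.0, 2.0], [1.0, 2.0], method="median")


def test_round_half_away():
    assert round_half_away(0.0167, 3) == 0.017
    assert round_half_away(81.45, 1) == 81.5
    assert round_half_away(2.5, 0) == 3.0
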