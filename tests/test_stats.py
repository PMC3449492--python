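"""Validation statistics against independent oracles and printed values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modaspects.stats import (
    ConfusionCounts,
    clopper_pearson,
    confusion_from_scores,
    confusion_stats,
    correlation_band,
    icc_band,
    icc_oneway,
    kruskal_across_raters,
    ranksum_groups,
    roc_auc,
    spearman_rho,
    threshold_sweep,
)


def _rank_average(values):
    """Tiny independent ranking oracle: average ranks for ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)

    def test_perfect_inverse(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1, 2, 2, 4, 5, 5, 5, 9]
        y = [2, 3, 3, 5, 4, 8, 8, 7]
        rx, ry = _rank_average(x), _rank_average(y)
        mx, my = np.mean(rx), np.mean(ry)
        num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
        )
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(num / den)

    def test_matches_scipy_including_pvalue(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        x = rng.integers(0, 15, 25).astype(float)
        y = x + rng.normal(0, 4, 25)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        # n=5 without ties: enumerate all 120 pairings by hand
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho_obs, p = spearman_rho(x, y)
        count = 0
        ry = np.array(y)
        for perm in itertools.permutations(range(5)):
            rho_perm = np.corrcoef(np.array(x)[list(perm)], ry)[0, 1]
            if abs(rho_perm) >= abs(rho_obs) - 1e-9:
                count += 1
        assert p == pytest.approx(count / 120)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), 3 * y + 1)
        assert rho1 == pytest.approx(rho2)


class TestIcc:
    def test_perfect_agreement(self):
        m = np.array([[1, 1, 1], [5, 5, 5], [9, 9, 9]])
        res = icc_oneway(m)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_all_identical_is_flagged_degenerate(self):
        res = icc_oneway(np.full((4, 3), 7.0))
        assert res.icc == 1.0
        assert res.degenerate

    def test_three_by_three_hand_computed_anova(self):
        # rows (subjects): means 2, 5, 8; grand mean 5
        # SSB = 3*(9+0+9) = 54, MSB = 27; SSW = 2+2+2 = 6, MSW = 1
        # ICC(1) = (27-1)/(27+2*1) = 26/29
        m = np.array([[1, 2, 3], [4, 5, 6], [7, 9, 8]])
        res = icc_oneway(m)
        assert res.icc == pytest.approx(26 / 29)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_pure_noise_icc_near_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(300, 3))  # no subject effect at all
        assert abs(icc_oneway(m).icc) < 0.1

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        m = rng.normal(10, 3, size=(20, 3))
        a = icc_oneway(m)
        b = icc_oneway(2.5 * m + 40.0)
        assert a.icc == pytest.approx(b.icc)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_matches_pingouin_icc1(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        m = rng.normal(10, 4, (15, 3)) + rng.normal(0, 1, (15, 3))
        res = icc_oneway(m)
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(15), 3),
                "r": list(range(3)) * 15,
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = ref[ref.Type == "ICC(1,1)"].iloc[0]
        assert res.icc == pytest.approx(row.ICC)
        assert res.p_value == pytest.approx(row.pval)

    def test_bad_shapes_raise(self):
        with pytest.raises(ValueError):
            icc_oneway(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc_oneway(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestConfusion:
    def test_childhood_printed_counts(self):
        sens, spec = confusion_stats(ConfusionCounts(tp=36, fp=9, tn=60, fn=9))
        assert round(100 * sens.value, 1) == 80.0
        assert round(100 * spec.value, 1) == 87.0

    def test_perinatal_printed_counts(self):
        sens, spec = confusion_stats(ConfusionCounts(tp=51, fp=6, tn=24, fn=9))
        assert round(100 * sens.value, 1) == 85.0
        assert round(100 * spec.value, 1) == 80.0

    def test_perfect_sensitivity_ci_reaches_one(self):
        sens, _ = confusion_stats(ConfusionCounts(tp=20, fp=1, tn=5, fn=0))
        assert sens.value == 1.0
        assert sens.ci_high == 1.0

    def test_empty_margin_raises(self):
        with pytest.raises(ValueError):
            confusion_stats(ConfusionCounts(tp=0, fp=3, tn=4, fn=0))

    def test_from_scores_threshold_rule(self):
        counts = confusion_from_scores([0, 4, 5, 9], [0, 1, 0, 1], 5)
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 1, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), data=st.data())
    def test_clopper_pearson_contains_estimate(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = clopper_pearson(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3], [0, 0, 1])[0] == pytest.approx(1.0)

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1])[0] == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 8, 20)
        labels = np.array([0] * 11 + [1] * 9)
        rng.shuffle(labels)
        auc, lo, hi = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos
            for q in neg
        )
        assert auc == pytest.approx(conc / (len(pos) * len(neg)))
        assert 0.0 <= lo <= auc <= hi <= 1.0

    def test_delong_interval_near_hanley_mcneil(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60) + np.array([0] * 30 + [1.5] * 30)
        labels = np.array([0] * 30 + [1] * 30)
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(scores, labels, method="delong")
        assert a1[0] == a2[0]
        assert a2[1] == pytest.approx(a1[1], abs=0.05)

    def test_auc_equals_trapezoid_over_sweep(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 31, 80)
        labels = (rng.random(80) < 0.4).astype(int)
        auc, *_ = roc_auc(scores, labels)
        table, _ = threshold_sweep(scores, labels)
        # close the curve at (0,0): the rule "score >= 31" predicts nothing
        fpr = np.array([1 - r["specificity"] for r in table] + [0.0])
        tpr = np.array([r["sensitivity"] for r in table] + [0.0])
        order = np.argsort(fpr)
        area = float(np.trapezoid(tpr[order], fpr[order]))
        assert auc == pytest.approx(area)


class TestThresholdSweep:
    def test_perfectly_separated_cohort_selects_five(self):
        scores = [1, 2, 3, 4, 5, 6, 7, 8]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]  # small < 5, large >= 5
        table, best = threshold_sweep(scores, labels)
        assert best == 5
        row = table[5]
        assert row["sensitivity"] == 1.0
        assert row["specificity"] == 1.0

    def test_threshold_zero_is_always_fully_sensitive(self):
        table, _ = threshold_sweep([0, 3, 10], [0, 1, 1])
        assert table[0]["threshold"] == 0
        assert table[0]["sensitivity"] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            threshold_sweep([1, 2], [1, 1])


class TestGroupComparisons:
    def test_identical_rater_distributions(self):
        col = np.arange(10.0)
        m = np.stack([col, col, col], axis=1)
        _, p = kruskal_across_raters(m)
        assert p > 0.95

    def test_degenerate_all_equal(self):
        assert kruskal_across_raters(np.full((5, 3), 4.0)) == (0.0, 1.0)

    def test_disjoint_groups_rank_sum(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        _, p = ranksum_groups(a, b)
        assert p < 0.001

    def test_kruskal_matches_hand_ranked_formula(self):
        # three rater columns, no ties: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2
        m = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 5.0], [8.0, 7.0, 9.0]])
        pooled = m.T.ravel().tolist()  # column-major: group by rater
        ranks = _rank_average(pooled)
        n = len(pooled)
        h = 0.0
        for j in range(3):
            r = ranks[3 * j: 3 * j + 3]
            h += 3 * (np.mean(r) - (n + 1) / 2) ** 2
        h *= 12 / (n * (n + 1))
        h_impl, _ = kruskal_across_raters(m)
        assert h_impl == pytest.approx(h)


class TestBands:
    @pytest.mark.parametrize(
        "rho, band",
        [(0.2, "weak"), (0.3, "weak"), (0.31, "moderate"), (0.7, "moderate"),
         (0.71, "strong"), (0.87, "strong"), (0.0, "none")],
    )
    def test_correlation_strength_cuts(self, rho, band):
        assert correlation_band(rho) == band

    @pytest.mark.parametrize(
        "icc, band",
        [(0.95, "almost perfect"), (0.81, "almost perfect"), (0.7, "substantial"),
         (0.5, "moderate"), (0.2, "below-moderate")],
    )
    def test_landis_koch_cuts(self, icc, band):
        assert icc_band(icc) == band
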