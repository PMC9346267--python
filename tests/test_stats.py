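"""Agreement and ROC statistics against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from ihcquant import (
    compare_auc,
    concordance_correlation,
    group_location_test,
    roc_analysis,
    spearman_correlation,
)


def _ccc_oracle(x, y):
    """Textbook Lin formula coded independently, 1/n moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def _auc_oracle(scores, labels):
    """Concordant-pair count (+ half ties) over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestConcordanceCorrelation:
    def test_identity_gives_one(self):
        assert concordance_correlation([1, 2, 3, 4], [1, 2, 3, 4]).ccc == pytest.approx(1.0)

    def test_mirrored_about_zero_gives_minus_one(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert concordance_correlation(x, -x).ccc == pytest.approx(-1.0)

    def test_textbook_example(self):
        """Hand evaluation of Lin's formula: x=(1,2,3,4), y=(1,2,3,6)
        gives 2*2 / (1.25 + 3.5 + 0.25) = 0.8."""
        res = concordance_correlation([1, 2, 3, 4], [1, 2, 3, 6])
        assert res.ccc == pytest.approx(0.8)
        assert res.category == "acceptable"

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert concordance_correlation(x, y).ccc == pytest.approx(
                _ccc_oracle(x, y), abs=1e-12
            )

    def test_never_exceeds_pearson_in_magnitude(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            x = rng.normal(loc=rng.normal(), scale=rng.uniform(0.5, 3), size=n)
            y = rng.normal(loc=rng.normal(), scale=rng.uniform(0.5, 3), size=n)
            r = sps.pearsonr(x, y).statistic
            assert abs(concordance_correlation(x, y).ccc) <= abs(r) + 1e-12

    def test_symmetric_and_joint_affine_invariant(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.3, size=20)
        a = concordance_correlation(x, y).ccc
        assert concordance_correlation(y, x).ccc == pytest.approx(a)
        assert concordance_correlation(3 * x + 2, 3 * y + 2).ccc == pytest.approx(a)

    @pytest.mark.parametrize(
        "ccc_value, category",
        [(0.799, "none"), (0.800, "acceptable"), (0.949, "acceptable"),
         (0.950, "strong"), (0.999, "strong")],
    )
    def test_category_thresholds_are_inclusive(self, ccc_value, category):
        """Agreement categories use >= at both the 0.800 and 0.950 cuts."""
        from ihcquant.stats import _ccc_category

        assert _ccc_category(ccc_value) == category

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.4, size=30)
        res = concordance_correlation(x, y)
        assert res.ci_low <= res.ccc <= res.ci_high

    def test_ci_coverage_near_nominal(self, rng):
        """For bivariate normal pairs with equal means and variances the
        population CCC equals the correlation; the 95% asymptotic CI should
        cover it at roughly the nominal rate."""
        rho = 0.8
        cover = 0
        n_rep, n = 400, 50
        cov = [[1.0, rho], [rho, 1.0]]
        for _ in range(n_rep):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            res = concordance_correlation(xy[:, 0], xy[:, 1])
            cover += res.ci_low <= rho <= res.ci_high
        assert 0.90 <= cover / n_rep <= 0.99

    def test_errors(self):
        with pytest.raises(ValueError):
            concordance_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            concordance_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            concordance_correlation([2, 2, 2], [2, 2, 2])


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_ranks(self, rng):
        """Pearson correlation of mid-ranks, ranks computed by hand."""

        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        for _ in range(20):
            x = rng.integers(0, 5, 15).astype(float)
            y = rng.integers(0, 5, 15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman_correlation(x, y)
            expected = sps.pearsonr(midranks(list(x)), midranks(list(y))).statistic
            assert rho == pytest.approx(expected, abs=1e-12)


class TestGroupLocationTest:
    def test_identical_groups_give_null_result(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = group_location_test([g, g, g, g])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_all_constant_data(self):
        stat, p = group_location_test([[5.0, 5.0], [5.0, 5.0]])
        assert (stat, p) == (0.0, 1.0)

    def test_separated_groups_matches_exact_rank_enumeration(self):
        """All of A below all of B (n=10 each): H takes its maximum for the
        rank configuration, and p is far below 0.001."""
        a = list(range(10))
        b = list(range(100, 110))
        stat, p = group_location_test([a, b])
        # exact H for untied two-group split with all A-ranks below B-ranks
        n, ranks_a, ranks_b = 20, range(1, 11), range(11, 21)
        h_max = 12 / (n * (n + 1)) * (
            sum(ranks_a) ** 2 / 10 + sum(ranks_b) ** 2 / 10
        ) - 3 * (n + 1)
        assert stat == pytest.approx(h_max)
        assert p < 0.001

    def test_anova_variant(self, rng):
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(5, 1, 20)
        stat, p = group_location_test([g1, g2], method="anova")
        assert p < 1e-6

    def test_errors(self):
        with pytest.raises(ValueError):
            group_location_test([[1.0, 2.0]])
        with pytest.raises(ValueError):
            group_location_test([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            group_location_test([[1, 2], [3, 4]], method="median")


class TestRocAnalysis:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert 3 < res.best_cutoff < 10

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 8, n).astype(float)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels, auto_direction=False)
            assert res.auc == pytest.approx(_auc_oracle(scores, labels), abs=1e-12)

    def test_youden_cutoff_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = rng.normal(size=40)
            labels = (rng.uniform(size=40) < sps.norm.cdf(scores)).astype(int)
            if labels.min() == labels.max():
                continue
            res = roc_analysis(scores, labels, auto_direction=False)
            # oracle: scan every midpoint, track best J, ties -> lower cutoff
            distinct = np.unique(scores)
            cuts = (distinct[:-1] + distinct[1:]) / 2
            best_j, best_c = -np.inf, None
            for c in cuts:
                sens = np.mean(scores[labels == 1] > c)
                spec = np.mean(scores[labels == 0] <= c)
                if sens + spec - 1 > best_j + 1e-12:
                    best_j, best_c = sens + spec - 1, c
            assert res.best_cutoff == pytest.approx(best_c)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(np.exp(scores), labels).auc
        assert a == pytest.approx(b)

    def test_negative_predictor_direction_flips(self):
        """A predictor where LOW values mark the positive class reports
        AUC > 0.5 with direction='lower'."""
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.direction == "lower"
        assert 0.3 < res.best_cutoff < 0.8  # on the original scale

    def test_delong_ci_brackets_auc(self, rng):
        scores = rng.normal(size=80) + np.repeat([0, 1], 40)
        labels = np.repeat([0, 1], 40)
        res = roc_analysis(scores, labels)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
        assert res.ci_high - res.ci_low > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


class TestCompareAuc:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert compare_auc(scores, scores, labels) == 1.0

    def test_monotone_transform_gives_p_one(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert compare_auc(scores, np.exp(scores) + 5, labels) == 1.0

    def test_detects_large_auc_gap(self, rng):
        """AUC ~0.95 vs ~0.60 predictors on 100 subjects per class are
        distinguished at p < 0.01 in nearly all replicates."""
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            labels = np.repeat([0, 1], 100)
            strong = rng.normal(size=200) + 2.33 * labels  # AUC ~ 0.95
            weak = rng.normal(size=200) + 0.36 * labels  # AUC ~ 0.60
            if compare_auc(strong, weak, labels) < 0.01:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2, 3], [1, 2], [0, 1, 1])
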