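"""Contingency-table and two-sample statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from steatomics.tableone import (
    ContingencyTable,
    fisher_exact_rxc,
    hwe_chi_square,
    pearson_chi_square,
    two_sample_t,
    two_sample_t_from_stats,
    wilcoxon_rank_sum,
)


def chi2_oracle(table):
    """Textbook O/E double loop, kept independent of the implementation."""
    t = np.asarray(table, float)
    rows, cols, n = t.sum(1), t.sum(0), t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = rows[i] * cols[j] / n
            stat += (t[i, j] - e) ** 2 / e
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def enumerate_fisher_oracle(table):
    """Exhaustive margin-preserving enumeration via per-row compositions."""
    t = np.asarray(table, int)
    rows, cols = t.sum(1), t.sum(0)

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    def log_prob(m):
        m = np.asarray(m)
        from scipy.special import gammaln

        return float(
            gammaln(rows + 1).sum()
            + gammaln(cols + 1).sum()
            - gammaln(t.sum() + 1)
            - gammaln(m + 1).sum()
        )

    lp_obs = log_prob(t)
    tail = total = 0.0
    for combo in itertools.product(*(compositions(r, len(cols)) for r in rows)):
        m = np.array(combo)
        if not np.array_equal(m.sum(0), cols):
            continue
        lp = log_prob(m)
        pr = math.exp(lp)
        total += pr
        if lp <= lp_obs + 1e-9:
            tail += pr
    return tail / total


class TestPearsonChiSquare:
    def test_identical_row_proportions_give_zero(self):
        res = pearson_chi_square(ContingencyTable([[10, 10], [20, 20]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_oracle_on_random_tables(self, rng):
        for _ in range(25):
            t = rng.multinomial(60, np.full(9, 1 / 9)).reshape(3, 3)
            t += 1  # keep expected counts positive
            res = pearson_chi_square(ContingencyTable(t))
            stat, p = chi2_oracle(t)
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_invariant_under_permutation_and_transposition(self, rng):
        t = np.array([[5, 9, 2], [11, 3, 8]])
        base = pearson_chi_square(ContingencyTable(t)).statistic
        assert pearson_chi_square(ContingencyTable(t[::-1])).statistic == pytest.approx(base)
        assert pearson_chi_square(ContingencyTable(t[:, ::-1])).statistic == pytest.approx(base)
        assert pearson_chi_square(ContingencyTable(t.T)).statistic == pytest.approx(base)

    def test_zero_margin_dropped_and_degenerate_rejected(self):
        with_zero = ContingencyTable([[5, 0, 7], [3, 0, 4]])
        res = pearson_chi_square(with_zero)
        assert res.df == 1
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chi_square(ContingencyTable([[5, 7], [0, 0]]))

    def test_p_monotone_in_statistic(self):
        # stronger association, same df -> smaller p
        weak = pearson_chi_square(ContingencyTable([[12, 8], [8, 12]]))
        strong = pearson_chi_square(ContingencyTable([[18, 2], [2, 18]]))
        assert strong.statistic > weak.statistic
        assert strong.p_value < weak.p_value


class TestHardyWeinberg:
    def test_exact_hwe_proportions_give_zero(self):
        res = hwe_chi_square(25, 50, 25)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_monomorphic_flagged_not_failed(self):
        res = hwe_chi_square(40, 0, 0)
        assert res.p_value == 1.0
        assert res.warning is not None

    def test_agrees_with_direct_formula(self, rng):
        for _ in range(20):
            n = 200
            q = rng.uniform(0.1, 0.9)
            g = rng.binomial(2, q, size=n)
            counts = [(g == k).sum() for k in (0, 1, 2)]
            if counts[0] == n or counts[2] == n:
                continue
            res = hwe_chi_square(*counts)
            phat = (2 * counts[0] + counts[1]) / (2 * n)
            exp = n * np.array([phat**2, 2 * phat * (1 - phat), (1 - phat) ** 2])
            stat = (((np.array(counts) - exp) ** 2) / exp).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.df == 1


class TestFisherExact:
    def test_two_by_two_diagonal(self):
        res = fisher_exact_rxc(ContingencyTable([[1, 0], [0, 1]]))
        assert res.p_value == pytest.approx(1.0)

    def test_hand_enumerated_hypergeometric(self):
        res = fisher_exact_rxc(ContingencyTable([[3, 1], [1, 3]]))
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_random_3x2_matches_bruteforce(self, rng):
        for _ in range(10):
            t = rng.integers(0, 7, size=(3, 2))
            tab = ContingencyTable(t + 1)
            assert fisher_exact_rxc(tab).p_value == pytest.approx(
                enumerate_fisher_oracle(tab.counts), abs=1e-10
            )

    def test_2x2_equals_classical_fisher(self, rng):
        # probability-ordering two-sided rule, as scipy implements for 2x2
        for _ in range(60):
            t = rng.integers(0, 11, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            ours = fisher_exact_rxc(ContingencyTable(t)).p_value
            _, ref = stats.fisher_exact(t, alternative="two-sided")
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_enumeration_guard(self):
        big = ContingencyTable([[300, 300], [200, 200]])
        with pytest.raises(ValueError, match="guard"):
            fisher_exact_rxc(big)


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.2878, abs=1e-4)

    def test_raw_equals_summary_path(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 20))
            b = rng.normal(loc=0.3, size=rng.integers(3, 20))
            raw = two_sample_t(a, b)
            summ = two_sample_t_from_stats(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
            assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_zero_variance(self):
        assert two_sample_t([2, 2, 2], [2, 2]).p_value == 1.0
        with pytest.raises(ValueError, match="pooled variance"):
            two_sample_t([2, 2, 2], [3, 3])


class TestWilcoxon:
    def test_identical_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5]).p_value == 1.0

    def test_close_to_exact_for_small_samples(self, rng):
        # scipy's exact Mann-Whitney distribution is the oracle
        for _ in range(20):
            a = rng.normal(size=8)
            b = rng.normal(loc=0.5, size=8)
            ours = wilcoxon_rank_sum(a, b).p_value
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert abs(ours - exact) < 0.02

    def test_power_at_one_sd_shift(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(size=50)
            b = rng.normal(loc=1.0, size=50)
            if wilcoxon_rank_sum(a, b).p_value < 0.05:
                rejections += 1
        assert rejections / reps > 0.99
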