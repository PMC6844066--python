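"""Statistics: exact-test oracles, descriptive stats, interobserver agreement."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pulmoflow import stats
from pulmoflow.exceptions import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedPercentError,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def wilcoxon_bruteforce(a, b):
    """Two-sided exact signed-rank p by enumerating every sign assignment."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2**n


def mann_whitney_bruteforce(x, y):
    """Two-sided exact rank-sum p by enumerating every group labeling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:n1].sum()
    mu = n1 * ranks.mean()
    combos = list(itertools.combinations(range(ranks.size), n1))
    count = sum(
        1 for c in combos if abs(sum(ranks[i] for i in c) - mu) >= abs(r_obs - mu) - 1e-9
    )
    return count / len(combos)


# ---------------------------------------------------------------------------
# describe
# ---------------------------------------------------------------------------

class TestDescribe:
    def test_hand_computed_mean_and_sem(self):
        mean, sem = stats.describe([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / np.sqrt(3.0), abs=1e-9)

    def test_constant_vector_has_zero_sem(self):
        assert stats.describe([4.0] * 6)[1] == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.describe([1.0])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_large_uniform_shift_n10(self):
        a = np.arange(10, dtype=float)
        b = a + 100.0
        _, p = stats.wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2.0 / 2**10, abs=1e-12)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateTestError):
            stats.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        a = rng.integers(0, 6, n).astype(float)  # integer data force ties and zeros
        b = rng.integers(0, 6, n).astype(float)
        if np.all(a == b):
            return
        _, p = stats.wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(wilcoxon_bruteforce(a, b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        stat, p = stats.wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        perm = rng.permutation(15)
        assert stats.wilcoxon_signed_rank(a, b)[1] == pytest.approx(
            stats.wilcoxon_signed_rank(a[perm], b[perm])[1]
        )

    def test_normal_approximation_above_exact_regime(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 40)
        b = a + rng.normal(0.5, 1, 40)
        _, p = stats.wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_groups_p_near_one(self):
        _, p = stats.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_fully_separated_five_vs_five(self):
        _, p = stats.mann_whitney([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2.0 / 252.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        _, p = stats.mann_whitney(x, y)
        assert p == pytest.approx(mann_whitney_bruteforce(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(50 + seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        stat, p = stats.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            stats.mann_whitney([], [1.0, 2.0])

    def test_normal_approximation_with_ties(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 10, 30).astype(float)
        y = rng.integers(2, 12, 25).astype(float)
        _, p = stats.mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_identical_conditions_statistic_zero(self):
        m = np.tile([3.0, 3.0, 3.0, 3.0], (5, 1))
        stat, p = stats.friedman(m)
        assert stat == 0.0 and p == 1.0

    def test_three_by_three_textbook_formula(self):
        m = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]])
        stat, _ = stats.friedman(m)
        # hand ranking: rows rank to (1,2,3), (1,2,3), (3,1,2); column rank sums 5,5,8
        n, k = 3, 3
        expected = 12.0 / (n * k * (k + 1)) * (25 + 25 + 64) - 3 * n * (k + 1)
        assert stat == pytest.approx(expected)

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan, 3.0], [2.0, 4.0, 6.0]])
        with pytest.raises(InvalidInputError):
            stats.friedman(m)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(InvalidInputError):
            stats.friedman(np.ones((5, 2)))


# ---------------------------------------------------------------------------
# interobserver agreement
# ---------------------------------------------------------------------------

class TestInterobserver:
    def test_perfect_agreement(self):
        rep = stats.interobserver([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert rep.mean_pct_diff == 0.0
        assert rep.dahlberg == 0.0
        assert rep.icc == pytest.approx(1.0)

    def test_hand_computed_dahlberg_fixture(self):
        rep = stats.interobserver([10.0, 20.0], [12.0, 18.0])
        assert rep.dahlberg == pytest.approx(np.sqrt(2.0), abs=1e-9)
        assert rep.relative_dahlberg == pytest.approx(100.0 * np.sqrt(2.0) / 15.0, abs=1e-9)

    def test_symmetric_in_observer_order(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(50, 10, 12)
        x2 = x1 * rng.lognormal(0, 0.05, 12)
        r12 = stats.interobserver(x1, x2)
        r21 = stats.interobserver(x2, x1)
        assert r12.dahlberg == pytest.approx(r21.dahlberg)
        assert r12.mean_pct_diff == pytest.approx(r21.mean_pct_diff)
        assert r12.icc == pytest.approx(r21.icc, abs=1e-9)

    def test_absolute_agreement_icc_invariant_under_common_shift(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(50, 10, 15)
        x2 = x1 + rng.normal(0, 2, 15)
        base = stats.interobserver(x1, x2).icc
        shifted = stats.interobserver(x1 + 100.0, x2 + 100.0).icc
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_multiplicative_noise_monte_carlo_envelope(self):
        # two observers with 5% CV multiplicative error, n=10 subjects
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = rng.normal(46, 8, 10)
            x1 = truth * rng.lognormal(0, 0.05, 10)
            x2 = truth * rng.lognormal(0, 0.05, 10)
            means.append(stats.interobserver(x1, x2).mean_pct_diff)
        assert 2.0 <= float(np.mean(means)) <= 9.0

    def test_zero_average_pair_rejected(self):
        with pytest.raises(UndefinedPercentError):
            stats.interobserver([1.0, -2.0], [1.0, 2.0])
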