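"""Cohort statistics: nonparametric paired tests and interobserver agreement.

The Wilcoxon signed-rank and Mann-Whitney U tests use exact null
distributions in the small-sample regime (computed by dynamic programming
over mid-ranks, so ties are handled inside the exact path) and a normal
approximation with continuity and tie correction above it.  The Friedman
test delegates to scipy (mid-ranks, chi-square approximation).

Interobserver agreement follows duplicate-measurement convention: mean and
SD of the unsigned percent difference from the pair average, the Dahlberg
error ``sqrt(sum(d²) / 2n)``, the relative Dahlberg error (percent of the
grand mean), and the intraclass correlation coefficient, by default
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
computed via pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedPercentError,
)

__all__ = [
    "describe",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "friedman",
    "interobserver",
    "AgreementReport",
]

#: Largest sample size for which the exact Wilcoxon null distribution is used.
WILCOXON_EXACT_MAX_N = 25
#: Largest combined sample size for which the exact Mann-Whitney null is used.
MANN_WHITNEY_EXACT_MAX_N = 20

# Shrout-Fleiss names -> pingouin's McGraw-Wong labels.
_ICC_LABELS = {
    "ICC1": "ICC(1,1)",
    "ICC2": "ICC(A,1)",  # two-way random, absolute agreement, single measurement
    "ICC3": "ICC(C,1)",  # two-way mixed, consistency, single measurement
    "ICC1k": "ICC(1,k)",
    "ICC2k": "ICC(A,k)",
    "ICC3k": "ICC(C,k)",
}


def describe(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("describe requires at least 2 observations")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank sum with integer doubled ranks.

    Enumerates the null distribution of W+ (sum of ranks of positive
    differences under random signs) by subset-sum dynamic programming, then
    returns P(|W+ − μ| ≥ |w − μ|) under the symmetric null.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    support = np.arange(total + 1)
    mu = total / 2.0
    mass = counts[np.abs(support - mu) >= abs(w2 - mu) - 1e-9].sum()
    return float(mass / counts.sum())


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded before ranking (classic Wilcoxon, not
    Pratt); tied absolute differences receive mid-ranks.  The null
    distribution is exact for n ≤ 25 remaining pairs and a normal
    approximation with continuity and tie correction above.  Returns
    ``(W, p)`` with ``W = min(W+, W−)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)

    if n <= WILCOXON_EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)  # mid-ranks doubled are integers
        p = _exact_signed_rank_p(ranks2, 2 * w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise DegenerateTestError("zero variance in signed-rank statistic")
        z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return statistic, min(float(p), 1.0)


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, r2_obs: float) -> float:
    """Two-sided exact p for the rank sum of group 1 over all labelings.

    ``ranks2`` are the pooled mid-ranks doubled to integers; dynamic
    programming over (group-1 size, rank sum) counts the labelings.
    """
    total = int(ranks2.sum())
    counts = np.zeros((n1 + 1, total + 1))
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[1:, r:] += counts[:-1, : total + 1 - r]
        counts = new
    dist = counts[n1]
    support = np.arange(total + 1)
    mu = n1 * total / ranks2.size / 1.0  # mean rank sum of group 1 (doubled scale)
    mass = dist[np.abs(support - mu) >= abs(r2_obs - mu) - 1e-9].sum()
    return float(mass / dist.sum())


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test for two independent groups.

    Mid-ranks for ties; exact null distribution (enumeration over labelings)
    for combined n ≤ 20, normal approximation with tie correction and
    continuity correction above.  Returns ``(U1, p)`` where U1 is the
    U statistic of the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= MANN_WHITNEY_EXACT_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_rank_sum_p(ranks2, n1, 2 * r1)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            raise DegenerateTestError("zero variance in rank-sum statistic")
        z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(max(z, 0.0))
    return float(u1), min(float(p), 1.0)


def friedman(matrix: np.ndarray) -> Tuple[float, float]:
    """Friedman test for repeated measures: subjects × (≥3) conditions.

    Mid-ranks within rows, chi-square approximation (scipy).  If every
    subject's measurements are identical across conditions the statistic is 0
    and p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise InvalidInputError("need a 2-D matrix with >= 2 subjects and >= 3 conditions")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError("missing cells are not allowed in the Friedman test")
    if np.all(m.max(axis=1) == m.min(axis=1)):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return float(stat), float(p)


@dataclass(frozen=True)
class AgreementReport:
    """Interobserver agreement summary for duplicate measurements."""

    mean_pct_diff: float
    sd_pct_diff: float
    dahlberg: float
    relative_dahlberg: float
    icc: float
    icc_variant: str = "ICC2"


def interobserver(
    x1: Sequence[float],
    x2: Sequence[float],
    icc_variant: str = "ICC2",
    signed: bool = False,
) -> AgreementReport:
    """Agreement metrics between two observers measuring the same subjects.

    Percent differences are taken relative to each pair's average, unsigned
    by default.  The Dahlberg error is ``sqrt(sum(d²) / 2n)`` in the input
    unit; the relative Dahlberg error expresses it as a percent of the grand
    mean.  ``icc_variant`` is a pingouin ICC type name ("ICC1", "ICC2",
    "ICC3", ...); ICC(2,1) is the default for two raters on the same
    subjects.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise InvalidInputError("observer vectors must be 1-D and of equal length")
    n = x1.size
    if n < 2:
        raise InsufficientDataError("need at least 2 measurement pairs")

    pair_means = (x1 + x2) / 2.0
    if np.any(pair_means == 0):
        raise UndefinedPercentError("a measurement pair averages to zero")
    pct = 100.0 * (x1 - x2) / pair_means
    if not signed:
        pct = np.abs(pct)

    d = x1 - x2
    dahlberg = float(np.sqrt(np.sum(d**2) / (2 * n)))
    grand_mean = float(np.mean(np.concatenate([x1, x2])))
    relative_dahlberg = 100.0 * dahlberg / grand_mean if grand_mean != 0 else np.nan

    if np.allclose(x1, x2):
        icc = 1.0
    else:
        import pingouin as pg

        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), 2),
                "rater": np.repeat(["obs1", "obs2"], n),
                "score": np.concatenate([x1, x2]),
            }
        )
        label = _ICC_LABELS.get(icc_variant, icc_variant)
        if label not in _ICC_LABELS.values():
            raise InvalidInputError(f"unknown ICC variant {icc_variant!r}")
        try:
            table = pg.intraclass_corr(
                data=long, targets="subject", raters="rater", ratings="score"
            )
            icc = float(table.loc[table["Type"] == label, "ICC"].iloc[0])
        except AssertionError:
            # the two-way ANOVA behind the ICC needs > 2 subjects
            icc = float("nan")

    return AgreementReport(
        mean_pct_diff=float(np.mean(pct)),
        sd_pct_diff=float(np.std(pct, ddof=1)),
        dahlberg=dahlberg,
        relative_dahlberg=float(relative_dahlberg),
        icc=icc,
        icc_variant=icc_variant,
    )
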