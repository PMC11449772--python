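"""Nonparametric comparison battery: paired Wilcoxon, Kruskal-Wallis with
Bonferroni-adjusted pairwise tests, Spearman correlation, and ICC.

Conventions chosen where the source software default is unknowable:
Wilcoxon uses the zero-discard rule with midrank ties; the ICC flavor
defaults to two-way random, absolute agreement, single measure; Spearman
p-values are exact permutation values for n <= 8 and t-approximate above.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateTestError",
    "UndefinedStatisticError",
    "wilcoxon_paired",
    "kruskal_wallis_bonferroni",
    "spearman",
    "icc",
]

SPEARMAN_EXACT_MAX_N = 8


class DegenerateTestError(ValueError):
    """The test statistic is undefined for these data."""


class UndefinedStatisticError(ValueError):
    """The requested quantity is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class despite the name

    statistic: float
    p_value: float
    n: int
    method: str
    adjusted: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired signed-rank test, zero-discard, midrank ties.

    All-zero differences make the statistic degenerate; a p-value of 1 is
    returned with ``extra['degenerate'] = True`` rather than raising, since
    identical samples carry no evidence of a difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = int(np.count_nonzero(diffs))
    if nonzero == 0:
        return TestResult(0.0, 1.0, len(x), "wilcoxon-signed-rank",
                          extra={"degenerate": True})
    if nonzero < 5:
        raise ValueError("need >= 5 nonzero paired differences")
    stat, p = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return TestResult(float(stat), float(p), nonzero, "wilcoxon-signed-rank")


def kruskal_wallis_bonferroni(
    groups: Mapping[object, Sequence[float]],
) -> Tuple[TestResult, "Dict[Tuple[object, object], TestResult]"]:
    """Omnibus Kruskal-Wallis H (tie-corrected) plus all pairwise two-sided
    Mann-Whitney comparisons, Bonferroni-adjusted by the number of pairs."""
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()
               if len(v) > 0}
    if len(samples) < 2:
        raise ValueError("need at least 2 nonempty groups")
    values = list(samples.values())
    n_total = sum(len(v) for v in values)
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        omnibus = TestResult(0.0, 1.0, n_total, "kruskal-wallis",
                             extra={"degenerate": True})
    else:
        h, p = sps.kruskal(*values)
        omnibus = TestResult(float(h), float(p), n_total, "kruskal-wallis")
    pairs = list(itertools.combinations(samples, 2))
    multiplier = len(pairs)
    pairwise: Dict[Tuple[object, object], TestResult] = {}
    for a, b in pairs:
        xa, xb = samples[a], samples[b]
        if np.all(np.concatenate([xa, xb]) == xa[0]):
            raw = 1.0
            stat = len(xa) * len(xb) / 2.0
        else:
            stat, raw = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        pairwise[(a, b)] = TestResult(
            float(stat), min(1.0, float(raw) * multiplier),
            len(xa) + len(xb), "mann-whitney-bonferroni", adjusted=True,
            extra={"p_raw": float(raw), "multiplier": multiplier},
        )
    return omnibus, pairwise


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p over all orderings of one rank vector."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Midrank Spearman correlation with a two-sided p-value.

    For n <= 8 the p-value is the exact permutation value over all orderings;
    for larger n the usual t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance input")
    rho, p = sps.spearmanr(x, y)
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _exact_spearman_p(x, y, float(rho))
        method = "spearman-exact"
    else:
        method = "spearman"
    return TestResult(float(rho), float(p), n, method)


def icc(
    ratings: np.ndarray,
    flavor: str = "icc2",
) -> TestResult:
    """Intraclass correlation of an n-subjects x k-raters matrix.

    ``icc2`` (default): two-way random effects, absolute agreement, single
    measure. ``icc3``: two-way mixed, consistency, single measure. The
    p-value is from F = MSR/MSE with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with k >= 2")
    n, k = m.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings must be complete and finite")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = float(((m - grand) ** 2).sum())
    ss_rows = float(k * ((row_means - grand) ** 2).sum())
    ss_cols = float(n * ((col_means - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0.0:
        raise UndefinedStatisticError("zero between-subject variance")

    if flavor == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif flavor == "icc3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC flavor {flavor!r}")
    value = 1.0 if denom == 0.0 else (msr - mse) / denom

    if mse == 0.0:
        p = 0.0
        f_stat = math.inf
    else:
        f_stat = msr / mse
        p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return TestResult(float(value), p, n, f"icc-{flavor}",
                      extra={"F": f_stat, "msr": msr, "msc": msc, "mse": mse})
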