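"""Classifier-comparison statistics over blocked accuracy tables.

Accuracies are arranged as blocks x methods (one block per participant x
test sentence).  The omnibus comparison is the Friedman rank test (with tie
correction); post-hoc comparisons use either mean-rank critical differences
or pairwise Wilcoxon signed-rank tests with Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AccuracyTable",
    "ComparisonReport",
    "friedman",
    "mean_rank_posthoc",
    "wilcoxon_pairwise",
    "pearson",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class AccuracyTable:
    """Blocks x methods accuracy matrix with labels."""

    values: np.ndarray
    method_names: list[str]
    block_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (blocks x methods)")
        n, k = self.values.shape
        if k < 2 or n < 2:
            raise ValueError("need at least 2 methods and 2 blocks")
        if np.isnan(self.values).any():
            raise ValueError("accuracy table has missing cells")
        if len(self.method_names) != k or len(self.block_ids) != n:
            raise ValueError("label lengths do not match the table shape")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AccuracyTable":
        return cls(df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.method_names, index=self.block_ids)


@dataclass
class ComparisonReport:
    friedman_stat: float
    friedman_p: float
    mean_ranks: np.ndarray
    rank_ci_halfwidth: float
    rank_significant: np.ndarray  # k x k boolean
    wilcoxon_adjusted_p: np.ndarray  # k x k, NaN diagonal
    method_names: list[str]
    alpha: float


def friedman(table: AccuracyTable, method: str = "chi2") -> tuple[float, float, np.ndarray]:
    """Friedman test with tie correction.

    Accuracies are ranked within each block (average ranks on ties).  With
    ``method='chi2'`` the tie-corrected statistic is referred to a
    chi-square distribution with k - 1 degrees of freedom; with
    ``method='exact'`` the p-value is the tail probability of the statistic
    under full enumeration of all (k!)^N equally likely tie-free within-block
    orderings (small tables only).  Returns (statistic, p-value, mean ranks).
    """
    X = table.values
    n, k = X.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    mean_ranks = ranks.mean(axis=0)
    rank_sums = ranks.sum(axis=0)
    # tie-robust form (Conover): denominator from the observed squared ranks
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    num = float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum())
    if a == c:  # all methods tied in every block
        return 0.0, 1.0, mean_ranks
    stat = (k - 1) * num / (a - c)
    if method == "exact":
        import itertools as it
        import math

        if math.factorial(k) ** n > 2_000_000:
            raise ValueError("table too large for exact enumeration")
        perms = np.array(list(it.permutations(range(1, k + 1))), dtype=float)
        idx = np.array(list(it.product(range(len(perms)), repeat=n)))
        null_rank_sums = perms[idx].sum(axis=1)
        # tie-free orderings: the denominator is constant
        a0 = n * k * (k + 1) * (2 * k + 1) / 6.0
        null_stats = (k - 1) * ((null_rank_sums - n * (k + 1) / 2.0) ** 2).sum(axis=1) / (a0 - c)
        p = float(np.mean(null_stats >= stat - 1e-12))
    elif method == "chi2":
        p = float(sps.chi2.sf(stat, k - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), p, mean_ranks


def mean_rank_posthoc(
    mean_ranks: np.ndarray,
    k: int,
    n_blocks: int,
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> dict:
    """Mean-rank pairwise comparisons with a normal-approximation critical
    difference.

    Under the Friedman null, the difference of two mean ranks has variance
    k(k+1)/(6 N); pair (i, j) is significant when |R_i - R_j| exceeds
    z_{1 - alpha'/2} * sqrt(k(k+1)/(6N)) with alpha' Bonferroni-divided by
    the number of pairs (or unadjusted when ``adjust='none'``).  Per-method
    intervals of half the critical difference are returned so that two
    methods are significant exactly when their intervals do not overlap.
    """
    mean_ranks = np.asarray(mean_ranks, dtype=float)
    m = k * (k - 1) // 2
    alpha_eff = alpha / m if adjust == "bonferroni" else alpha
    z = sps.norm.ppf(1 - alpha_eff / 2)
    # var(R_i - R_j) = 2 * k(k+1)/(12 N)
    cd = z * np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    significant = diff > cd
    np.fill_diagonal(significant, False)
    return {
        "critical_difference": float(cd),
        "ci_halfwidth": float(cd / 2),
        "significant": significant,
        "mean_ranks": mean_ranks,
        "alpha": alpha,
        "adjust": adjust,
    }


def wilcoxon_pairwise(table: AccuracyTable, correction: str = "bonferroni") -> np.ndarray:
    """Pairwise two-sided Wilcoxon signed-rank tests on paired blocks.

    Zero differences are dropped (classical Wilcoxon); the exact null
    distribution is used for n <= 25 informative pairs (when free of rank
    ties), otherwise the normal approximation with tie and continuity
    correction.  Raw p-values are multiplied by the number of comparisons
    m = k(k-1)/2 and capped at 1.  Returns a symmetric k x k matrix with a
    NaN diagonal.
    """
    X = table.values
    n, k = X.shape
    m = k * (k - 1) // 2
    out = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        d = X[:, i] - X[:, j]
        d = d[d != 0]
        if d.size == 0:
            logger.info("wilcoxon %s vs %s: all differences zero",
                        table.method_names[i], table.method_names[j])
            raw = 1.0
        else:
            ties = len(np.unique(np.abs(d))) < len(d)
            method = "exact" if (len(d) <= 25 and not ties) else "approx"
            kwargs = {"correction": True} if method == "approx" else {}
            raw = float(
                sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method=method, **kwargs).pvalue
            )
        adj = min(1.0, raw * m) if correction == "bonferroni" else raw
        out[i, j] = out[j, i] = adj
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-d arrays with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_methods(table: AccuracyTable, alpha: float = 0.05) -> ComparisonReport:
    """Full comparison: Friedman omnibus + mean-rank and Wilcoxon post-hocs."""
    stat, p, mean_ranks = friedman(table)
    n, k = table.values.shape
    post = mean_rank_posthoc(mean_ranks, k, n, alpha=alpha)
    wil = wilcoxon_pairwise(table)
    return ComparisonReport(
        friedman_stat=stat,
        friedman_p=p,
        mean_ranks=mean_ranks,
        rank_ci_halfwidth=post["ci_halfwidth"],
        rank_significant=post["significant"],
        wilcoxon_adjusted_p=wil,
        method_names=list(table.method_names),
        alpha=alpha,
    )
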