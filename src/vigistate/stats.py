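"""Nonparametric group statistics for cohort-level comparisons.

Thin, convention-pinning wrappers around scipy: Mann-Whitney U with exact
enumeration on small tie-free samples and a tie/continuity-corrected normal
approximation otherwise; Spearman correlation with exact permutation
p-values at small n; Pearson chi-square on contingency tables (with the
option of halving the upper-tail p for a directed hypothesis, the reporting
convention used with directed frequency shifts); Student t-tests; and a
median split with balanced assignment of median-tied values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as ss

EXACT_MW_MAX_N = 16   # exact Mann-Whitney enumeration limit (total n, no ties)
EXACT_SPEARMAN_MAX_N = 9


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    tail: str                  # "two-sided", "greater", "less"
    n: tuple[int, ...]
    z: Optional[float] = None  # normal-approximation deviate where applicable
    df: Optional[float] = None

    def as_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": round(float(self.statistic), 6),
            "p_value": round(float(self.p_value), 6),
            "tail": self.tail,
            "n": list(self.n),
        }
        if self.z is not None:
            out["z"] = round(float(self.z), 6)
        if self.df is not None:
            out["df"] = float(self.df)
        return out


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    tail: str = "two-sided",
    method: str = "auto",
) -> TestResult:
    """Mann-Whitney U test with midrank ties.

    ``tail='greater'`` tests whether values in ``a`` are stochastically
    larger than in ``b``.  With ``method='auto'`` the p-value is exact (full
    enumeration of rank configurations) when the pooled sample has at most
    16 observations and no ties, and a tie-corrected normal approximation
    with continuity correction otherwise.  The reported statistic is the U
    of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        method = ("exact" if pooled.size <= EXACT_MW_MAX_N and not _has_ties(pooled)
                  else "asymptotic")
    res = ss.mannwhitneyu(a, b, alternative=tail, method=method,
                          use_continuity=True)
    z = None
    if method == "asymptotic":
        # recover the continuity/tie-corrected deviate for reporting
        n1, n2 = a.size, b.size
        u = float(res.statistic)
        mu = n1 * n2 / 2.0
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        if sigma > 0:
            z = (u - mu - 0.5 * np.sign(u - mu)) / sigma
    return TestResult(method=f"mann-whitney-u ({method})",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      tail=tail, n=(a.size, b.size), z=z)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, tail: str) -> float:
    """Exact permutation p for Spearman's rho (midranks), all n! relabelings."""
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        raise ValueError("constant input vector")
    obs = float(rx_c @ ry_c)  # rho is monotone in this inner product
    perms = np.array(list(permutations(range(x.size))))
    vals = (ry_c[perms] @ rx_c)
    eps = 1e-9 * max(1.0, abs(obs))
    if tail == "greater":
        count = (vals >= obs - eps).sum()
    elif tail == "less":
        count = (vals <= obs + eps).sum()
    else:
        count = (np.abs(vals) >= abs(obs) - eps).sum()
    return float(count / len(vals))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two-sided",
    method: str = "auto",
) -> TestResult:
    """Spearman rank correlation with midranks.

    Exact permutation p-value for n <= 9 (``method='auto'``), otherwise the
    t-distribution approximation.  ``tail='greater'`` tests rho > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector")
    rho = float(ss.spearmanr(x, y).statistic)
    if method == "auto":
        method = "exact" if x.size <= EXACT_SPEARMAN_MAX_N else "approx"
    if method == "exact":
        p = _spearman_exact_p(x, y, tail)
    else:
        p = float(ss.spearmanr(x, y, alternative=tail).pvalue)
    return TestResult(method=f"spearman ({method})", statistic=rho,
                      p_value=p, tail=tail, n=(x.size,))


def chi_square_independence(
    table: Sequence[Sequence[float]], tail: str = "two-sided"
) -> TestResult:
    """Pearson chi-square test of independence on a 2 x k table.

    ``tail='one-sided'`` halves the upper-tail p-value — the reporting
    convention for a directed hypothesis about which group is shifted toward
    which categories.  Warns when any expected count falls below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("expected a 2 x k contingency table")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("table has a zero margin")
    stat, p, df, expected = ss.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("expected counts below 5; chi-square approximation is "
                      "unreliable", stacklevel=2)
    if tail in ("one-sided", "one"):
        p = p / 2.0
        tail = "one-sided"
    else:
        tail = "two-sided"
    return TestResult(method="chi-square", statistic=float(stat),
                      p_value=float(p), tail=tail,
                      n=tuple(int(v) for v in obs.sum(axis=1)), df=float(df))


def t_test(
    a: Sequence[float], b: Sequence[float],
    tail: str = "two-sided", equal_var: bool = True,
) -> TestResult:
    """Two-sample Student (default) or Welch t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = ss.ttest_ind(a, b, equal_var=equal_var, alternative=tail)
    return TestResult(method="t-test" if equal_var else "welch-t",
                      statistic=float(res.statistic), p_value=float(res.pvalue),
                      tail=tail, n=(a.size, b.size), df=float(res.df))


@dataclass
class MedianSplit:
    """Median-split result: threshold and the index partition."""

    threshold: float
    high: np.ndarray   # indices with values above the median
    low: np.ndarray    # indices with values below the median


def median_split(values: Sequence[float]) -> MedianSplit:
    """Split subjects at the sample median of ``values``.

    Values strictly above the median go to the high group, strictly below to
    the low group; values equal to the median are assigned alternately
    (starting with the currently smaller group) so that, as far as possible,
    the two groups end up balanced.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least two values")
    thr = float(np.median(v))
    high = list(np.flatnonzero(v > thr))
    low = list(np.flatnonzero(v < thr))
    tied = np.flatnonzero(v == thr)
    if tied.size == v.size:
        warnings.warn("all values equal the median; split is arbitrary",
                      stacklevel=2)
    for idx in tied:
        if len(low) <= len(high):
            low.append(int(idx))
        else:
            high.append(int(idx))
    return MedianSplit(threshold=thr,
                       high=np.array(sorted(high), dtype=int),
                       low=np.array(sorted(low), dtype=int))
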