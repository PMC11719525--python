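"""Nonparametric tests: exact Wilcoxon signed-rank and Steel-Dwass all-pairs.

The signed-rank test is exact (full sign-assignment null distribution) for
n <= 25 untied differences and falls back to a tie-corrected normal
approximation with continuity correction otherwise; the method used is
recorded in the result.  The Steel-Dwass procedure compares every pair of
groups by tie-corrected pairwise rank sums referred to the studentized-range
distribution with k groups and infinite degrees of freedom (statistic x
sqrt(2) convention), matching the conventional R implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 25


@dataclass
class SignedRankResult:
    p_value: float
    statistic: float  # W: sum of positive-signed ranks
    n: int  # non-zero differences used
    method: str  # "exact" | "normal" | "degenerate"


def _exact_signed_rank_p(w: float, n: int) -> float:
    """Two-sided p for W over the 2^n equiprobable sign assignments.

    Ranks are the untied integers 1..n, so the null distribution of W is the
    distribution of a random subset sum, computed by convolution (equivalent
    to full enumeration of the 2^n sign vectors).
    """
    tot = n * (n + 1) // 2
    counts = np.zeros(tot + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r]
    counts /= 2.0**n
    w = int(round(w))
    lower = counts[: w + 1].sum()
    upper = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def exact_wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; |differences| are midranked on ties.
    All-zero differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return SignedRankResult(p_value=1.0, statistic=0.0, n=0, method="degenerate")
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= EXACT_MAX_N and not has_ties:
        return SignedRankResult(
            p_value=_exact_signed_rank_p(w, n), statistic=w, n=n, method="exact"
        )
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return SignedRankResult(p_value=1.0, statistic=w, n=n, method="degenerate")
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return SignedRankResult(p_value=p, statistic=w, n=n, method="normal")


@dataclass
class GroupTestResult:
    """All-pairs comparison table: one row per group pair."""

    table: pd.DataFrame  # columns: group_a, group_b, statistic, p_value
    k: int

    def p(self, a: str, b: str) -> float:
        t = self.table
        row = t[
            ((t.group_a == a) & (t.group_b == b))
            | ((t.group_a == b) & (t.group_b == a))
        ]
        if row.empty:
            raise KeyError(f"no comparison {a} vs {b}")
        return float(row.p_value.iloc[0])


def steel_dwass(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> GroupTestResult:
    """Steel-Dwass all-pairs multiple comparison over k >= 2 groups.

    For each pair, pooled midranks give the rank sum of the first group,
    standardized with the tie-corrected variance and referred to the
    studentized-range distribution (q = |t| * sqrt(2), k groups, inf df).
    A constant pooled pair yields p = 1.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    rows = []
    for i, j in combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        ni, nj = gi.size, gj.size
        pooled = np.concatenate([gi, gj])
        n = ni + nj
        ranks = sps.rankdata(pooled)
        r1 = ranks[:ni].sum()
        expect = ni * (n + 1) / 2.0
        var = ni * nj / (n * (n - 1.0)) * ((ranks**2).sum() - n * (n + 1) ** 2 / 4.0)
        if var <= 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = (r1 - expect) / np.sqrt(var)
            p = float(sps.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, np.inf))
            p = min(1.0, p)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": float(t_stat),
                "p_value": p,
            }
        )
    return GroupTestResult(table=pd.DataFrame(rows), k=k)
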