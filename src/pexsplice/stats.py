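"""Nonparametric test battery for group comparison of splicing features.

Implemented from first principles (scipy supplies only distribution
functions and mid-ranking): tie-corrected Kruskal-Wallis, Nemenyi post-hoc
on mean ranks (studentized-range flavor), Mann-Whitney U with exact
enumeration for small untied samples and a tie- and continuity-corrected
normal approximation otherwise, five-number summaries, and a feature-wise
group-comparison runner.

Conventions: all tests are two-sided by default with alpha = 0.05; a
feature whose values are identical across all observations returns the
degenerate H = 0, p = 1 rather than dividing by zero; quartiles use linear
interpolation between order statistics (the common "type 7" rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata, studentized_range

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> Tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H test.

    Mid-ranks over the pooled sample; ``H = [12/(N(N+1)) * sum n_g R_g^2 -
    3(N+1)] / C`` with the tie correction ``C = 1 - sum(t^3 - t)/(N^3 - N)``;
    p from the chi-square distribution with k-1 degrees of freedom.  If all
    pooled values are equal, returns ``H = 0, p = 1`` by convention.
    """
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrs):
        if a.size == 0:
            raise StatsError(f"group {i} is empty")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    if n_total < 3:
        raise StatsError("need at least three observations in total")
    df = len(arrs) - 1
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    ranks = rankdata(pooled)  # mid-ranks
    h = 0.0
    pos = 0
    for a in arrs:
        r = ranks[pos : pos + a.size]
        h += a.size * (r.mean() ** 2)
        pos += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    c = 1.0 - float(((tie_counts**3 - tie_counts).sum()) / (n_total**3 - n_total))
    if c == 0.0:
        return 0.0, df, 1.0
    h /= c
    return float(h), df, float(chi2_dist.sf(h, df))


# ---------------------------------------------------------------------------
# Nemenyi post hoc


def nemenyi_posthoc(groups: Sequence[Sequence[float]]) -> np.ndarray:
    """Pairwise Nemenyi test on mean ranks (studentized-range flavor).

    ``q_ij = |R_i - R_j| / sqrt(N(N+1)/12 * (1/n_i + 1/n_j))`` compared as
    ``q_ij * sqrt(2)`` against the studentized-range distribution with k
    groups and infinite degrees of freedom.  Returns a symmetric p-value
    matrix with unit diagonal.
    """
    k = len(groups)
    if k < 3:
        raise StatsError(
            "Nemenyi needs at least three groups; use mann_whitney_u for two"
        )
    arrs = [np.asarray(g, dtype=float) for g in groups]
    sizes = np.array([a.size for a in arrs])
    if np.any(sizes == 0):
        raise StatsError("empty group")
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = rankdata(pooled)
    means = []
    pos = 0
    for a in arrs:
        means.append(ranks[pos : pos + a.size].mean())
        pos += a.size
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            q = abs(means[i] - means[j]) / se if se > 0 else 0.0
            pij = float(studentized_range.sf(q * math.sqrt(2.0), k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pij)
    return p


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> Tuple[int, ...]:
    """Distribution of U under H0: counts of rank subsets per U value.

    ``f(n, m, u)`` = number of ways to choose ranks for the first sample of
    size ``n`` against ``m`` others with U statistic exactly ``u``; the
    standard recursion ``f(n,m,u) = f(n-1,m,u-m) + f(n,m-1,u)``.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # largest value in first sample: contributes m? no —
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    # recursion over whether the largest observation belongs to sample 1
    for u, c in enumerate(a):
        if c:
            out[u + m] += c
    for u, c in enumerate(b):
        if c:
            out[u] += c
    return tuple(out)


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> Tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, p)`` with ``U = min(U_a, U_b)``.

    ``mode="exact"`` enumerates the full null distribution of U (valid
    without ties); ``"approx"`` uses the normal approximation with tie and
    continuity corrections; ``"auto"`` picks exact when ``n_a + n_b <=
    exact_limit`` and the pooled sample is tie-free.  Identical samples
    yield ``p = 1``.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    na, nb = xa.size, xb.size
    if na == 0 or nb == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([xa, xb])
    ranks = rankdata(pooled)
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u_min = min(u_a, u_b)

    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        mode = "exact" if (na + nb <= exact_limit and not has_ties) else "approx"
    if mode == "exact":
        if has_ties:
            raise StatsError("exact enumeration is only valid without ties")
        counts = np.array(_u_counts(na, nb), dtype=float)
        total = counts.sum()
        cdf = counts.cumsum() / total
        sf_from = lambda u: counts[int(u):].sum() / total  # noqa: E731
        if alternative == "two-sided":
            p = min(1.0, 2.0 * cdf[int(u_min)])
        elif alternative == "less":
            # A tends smaller than B <=> U_a small
            p = cdf[int(u_a)]
        elif alternative == "greater":
            p = sf_from(u_a)
        else:
            raise StatsError(f"unknown alternative {alternative!r}")
        return float(u_min), float(p)
    if mode != "approx":
        raise StatsError(f"unknown mode {mode!r}")

    n = na + nb
    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u_min), 1.0  # all observations tied
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (u_min - mu + 0.5) / sd  # continuity correction toward the mean
        p = min(1.0, 2.0 * norm.cdf(z))
    elif alternative == "less":
        z = (u_a - mu + 0.5) / sd
        p = float(norm.cdf(z))
    elif alternative == "greater":
        z = (u_a - mu - 0.5) / sd
        p = float(norm.sf(z))
    else:
        raise StatsError(f"unknown alternative {alternative!r}")
    return float(u_min), float(p)


# ---------------------------------------------------------------------------
# summaries and the runner


def five_number_summary(x: Sequence[float]) -> Tuple[float, float, float, float, float]:
    """(min, Q1, median, Q3, max) with linearly interpolated quartiles."""
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise StatsError("empty sample")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(v) for v in q)  # type: ignore[return-value]


@dataclass
class GroupComparisonResult:
    feature: str
    group_n: Dict[str, int]
    group_summary: Dict[str, Tuple[float, float, float, float, float]]
    kw_h: float
    kw_df: int
    kw_p: float
    nemenyi_p: Optional[pd.DataFrame] = None  # only when KW p < alpha
    mwu_u: Optional[float] = None  # total-PE vs CE
    mwu_p: Optional[float] = None
    n_missing: int = 0


def compare_groups(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    group_col: str = "group",
    ce_label: str = "CE",
    pe_labels: Optional[Sequence[str]] = None,
) -> List[GroupComparisonResult]:
    """Feature-wise nonparametric battery over a per-exon feature table.

    For every numeric feature column: Kruskal-Wallis across the groups,
    Nemenyi pairwise p-values only when the KW test is significant at
    ``alpha``, and a Mann-Whitney U comparing the pooled pseudoexon groups
    ("total PE") against the canonical-exon group.  Missing values are
    dropped per feature with counts recorded; a feature with fewer than two
    non-empty groups is skipped with a warning.
    """
    if group_col not in table.columns:
        raise StatsError(f"table lacks a {group_col!r} column")
    labels = [g for g in table[group_col].unique()]
    if pe_labels is None:
        pe_labels = [g for g in labels if g != ce_label]
    results: List[GroupComparisonResult] = []
    features = [
        c for c in table.columns
        if c != group_col and pd.api.types.is_numeric_dtype(table[c])
    ]
    for feat in features:
        col = table[[group_col, feat]]
        n_missing = int(col[feat].isna().sum())
        col = col.dropna()
        by_group = {
            g: col.loc[col[group_col] == g, feat].to_numpy(dtype=float)
            for g in labels
        }
        by_group = {g: v for g, v in by_group.items() if v.size > 0}
        if len(by_group) < 2:
            logger.warning("feature %r skipped: fewer than two non-empty groups", feat)
            continue
        names = list(by_group)
        h, df, p = kruskal_wallis([by_group[g] for g in names])
        res = GroupComparisonResult(
            feature=feat,
            group_n={g: int(v.size) for g, v in by_group.items()},
            group_summary={g: five_number_summary(v) for g, v in by_group.items()},
            kw_h=h, kw_df=df, kw_p=p, n_missing=n_missing,
        )
        if p < alpha and len(names) >= 3:
            res.nemenyi_p = pd.DataFrame(
                nemenyi_posthoc([by_group[g] for g in names]),
                index=names, columns=names,
            )
        pe_vals = np.concatenate(
            [by_group[g] for g in names if g in pe_labels]
        ) if any(g in pe_labels for g in names) else np.array([])
        if ce_label in by_group and pe_vals.size:
            res.mwu_u, res.mwu_p = mann_whitney_u(pe_vals, by_group[ce_label])
        results.append(res)
    return results
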