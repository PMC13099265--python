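"""Nonparametric statistics shared across the pipeline.

Implements the paired Wilcoxon signed-rank test and the two-sample Wilcoxon
rank-sum (Mann-Whitney) test with exact small-sample null distributions, the
Kruskal-Wallis + Dunn post-hoc procedure with Benjamini-Hochberg correction,
and a compact letter display for group comparisons.

Exact distributions are computed by generating-function convolution, which
enumerates the same equiprobable outcomes (sign assignments, rank subsets) as
a literal enumeration but in polynomial time. Midranks from ties are handled
by doubling ranks to integers before convolving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignedRankResult",
    "RankSumResult",
    "paired_signed_rank",
    "rank_sum",
    "KwDunnResult",
    "kw_dunn",
    "compact_letter_display",
    "bh_adjust",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Exact null distributions
# ---------------------------------------------------------------------------

def _convolve_signed(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution (counts) of the doubled signed-rank statistic."""
    r2 = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    upper = 0
    for r in r2:
        new = counts.copy()
        new[r : upper + r + 1] += counts[0 : upper + 1]
        counts = new
        upper += r
    return counts, total


@dataclass
class SignedRankResult:
    """Paired Wilcoxon signed-rank test outcome."""

    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int
    n_zero_dropped: int
    method: str  # "exact" | "normal" | "degenerate"
    degenerate: bool = False

    def __iter__(self):  # allow tuple unpacking (stat, p)
        yield self.statistic
        yield self.p_value


def paired_signed_rank(x: Sequence[float], y: Sequence[float],
                       exact_max_n: int = 25) -> SignedRankResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original reduce-n convention)
    and reported. The null distribution of W+ is exact — all 2^n sign
    assignments of the midranks — for n <= `exact_max_n`; otherwise a normal
    approximation with continuity and (implicit, via midranks) tie correction
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return SignedRankResult(0.0, 1.0, 0, n_zero, "degenerate", True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        counts, total = _convolve_signed(ranks)
        denom = counts.sum()
        w2 = int(np.rint(2.0 * w_plus))
        cdf = counts[: w2 + 1].sum() / denom
        sf = counts[w2:].sum() / denom
        p = min(1.0, 2.0 * min(cdf, sf))
        return SignedRankResult(w_plus, p, n, n_zero, "exact")
    mu = ranks.sum() / 2.0
    sigma = np.sqrt(np.sum(ranks ** 2) / 4.0)
    if sigma == 0:
        return SignedRankResult(w_plus, 1.0, n, n_zero, "degenerate", True)
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return SignedRankResult(w_plus, p, n, n_zero, "normal")


def _mann_whitney_exact_counts(n: int, m: int) -> np.ndarray:
    """counts[u] = number of arrangements with Mann-Whitney U = u.

    Classic partition DP: U ranges over 0..n*m and the counts are the
    Gaussian-binomial coefficients of C(n+m, n).
    """
    size = n * m + 1
    arr = np.zeros(size, dtype=np.float64)
    arr[0] = 1.0
    # [n+m choose n]_q = prod_{i=1..n} (1 - q^{m+i}) / (1 - q^i); each step
    # multiplies by one numerator factor then divides by one denominator
    # factor, keeping the array integral (it is the Gaussian binomial
    # [m+i choose i]_q after step i).
    for i in range(1, n + 1):
        s = m + i
        if s < size:
            arr[s:] -= arr[: size - s].copy()
        for j in range(i, size):  # division by (1 - q^i): cumulative add
            arr[j] += arr[j - i]
    return arr


@dataclass
class RankSumResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) outcome."""

    u_statistic: float  # U for the first sample
    p_value: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal"
    direction: int  # sign of (median rank of x - expectation); +1 x higher


def rank_sum(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact when min(n, m) <= `exact_max_n` and there are no cross-sample ties;
    tie-corrected normal approximation with continuity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[:n].sum()
    u = rx - n * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    direction = int(np.sign(u - n * m / 2.0))
    if min(n, m) <= exact_max_n and not has_ties:
        counts = _mann_whitney_exact_counts(n, m)
        denom = counts.sum()
        ui = int(np.rint(u))
        cdf = counts[: ui + 1].sum() / denom
        sf = counts[ui:].sum() / denom
        p = min(1.0, 2.0 * min(cdf, sf))
        return RankSumResult(u, p, n, m, "exact", direction)
    mu = n * m / 2.0
    nt = n + m
    _, t = np.unique(pooled, return_counts=True)
    tie_term = np.sum(t ** 3 - t) / (nt * (nt - 1))
    sigma2 = n * m / 12.0 * (nt + 1 - tie_term)
    if sigma2 <= 0:
        return RankSumResult(u, 1.0, n, m, "normal", 0)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankSumResult(u, p, n, m, "normal", direction)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + compact letters
# ---------------------------------------------------------------------------

def compact_letter_display(groups: Sequence[str],
                           significant_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Assign letters such that groups sharing no letter differ significantly.

    Insert-and-absorb over the significance graph with deterministic group
    ordering (input order). Each letter corresponds to a maximal set of
    groups with no significant pair among them.
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    sets: list[set[str]] = [set(groups)]
    for pair in sorted(sig, key=lambda fs: tuple(sorted(fs))):
        a, b = sorted(pair)
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb subsets
        new_sets.sort(key=len, reverse=True)
        kept: list[set[str]] = []
        for s in new_sets:
            if not any(s <= k for k in kept):
                kept.append(s)
        sets = kept
    # deterministic letter order: by first member in group order
    order_idx = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order_idx[g] for g in s) if s else len(groups))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {g: [] for g in groups}
    for i, s in enumerate(sets):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in s:
            letters[g].append(ch)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


@dataclass
class KwDunnResult:
    """Kruskal-Wallis omnibus with Dunn's post hoc comparisons."""

    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group1, group2, z, p, p_adj, significant
    letters: dict[str, str]
    alpha: float = 0.05
    group_sizes: dict[str, int] = field(default_factory=dict)


def kw_dunn(values: Sequence[float], group_labels: Sequence,
            alpha: float = 0.05) -> KwDunnResult:
    """Kruskal-Wallis test with Dunn's post hoc z-tests and BH correction.

    Dunn's z for groups i, j uses mean ranks over the pooled sample with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)):

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))

    Letters follow the compact-letter-display convention: groups that share
    no letter differ at BH-adjusted p < alpha.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("kw_dunn requires at least 2 groups")
    by_group = {g: values[labels == g] for g in uniq}
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    kw_stat, kw_p = sps.kruskal(*[by_group[g] for g in uniq])

    n_total = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in uniq}
    _, t = np.unique(values, return_counts=True)
    tie_t = np.sum(t ** 3 - t) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_t

    rows = []
    for g1, g2 in combinations(uniq, 2):
        n1, n2 = by_group[g1].size, by_group[g2].size
        se = np.sqrt(var_base * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = bh_adjust(pw["p"].to_numpy())
    pw["significant"] = pw["p_adj"] < alpha
    sig_pairs = {
        (r.group1, r.group2) for r in pw.itertuples() if r.significant
    }
    letters = compact_letter_display(uniq, sig_pairs)
    return KwDunnResult(
        kw_statistic=float(kw_stat), kw_p=float(kw_p), pairwise=pw,
        letters=letters, alpha=alpha,
        group_sizes={g: int(by_group[g].size) for g in uniq},
    )
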