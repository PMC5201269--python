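"""Exact set-overlap statistics implemented from first principles.

One-sided (upper-tail) hypergeometric enrichment test — the "Fisher exact
test" in its enrichment orientation — the Mann-Whitney U test with exact
small-sample enumeration, and Venn region counts. Binomial coefficients are
computed in log space via lgamma; tail sums use log-sum-exp.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger("chapnet")

MANN_WHITNEY_EXACT_LIMIT = 12  # combined sample size for full enumeration


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table parameterized as (k, n, K, N).

    k = |A ∩ B|, n = |A|, K = |B|, N = universe size. Cells:
    a = k, b = n - k, c = K - k, d = N - n - K + k.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        k, n, K, N = self.k, self.n, self.K, self.N
        if not (0 <= k <= min(n, K)):
            raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
        if n > N or K > N:
            raise ValueError(f"need n, K <= N; got n={n}, K={K}, N={N}")
        if N - n - K + k < 0:
            raise ValueError(
                f"cell d = N-n-K+k = {N - n - K + k} < 0 for (k={k}, n={n}, K={K}, N={N})"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.k, self.n - self.k, self.K - self.k, self.N - self.n - self.K + self.k)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: float
    tail: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")

    @property
    def stars(self) -> str:
        """Significance annotation: * for p<0.05, ** for p<0.01."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


# ---------------------------------------------------------------------------
# Hypergeometric
# ---------------------------------------------------------------------------


def _log_binom(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _logsumexp(vals: Sequence[float]) -> float:
    m = max(vals)
    if m == -math.inf:
        return -math.inf
    return m + math.log(sum(math.exp(v - m) for v in vals))


def hypergeom_log_pmf(i: int, n: int, K: int, N: int) -> float:
    """log P(X = i) for X ~ Hypergeometric(N, K, n)."""
    return _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> TestResult:
    """P(X >= k) for the overlap X of a size-n and a size-K set in a size-N universe.

    Exact one-sided enrichment probability: the sum over i = k .. min(n, K)
    of C(K, i) C(N-K, n-i) / C(N, n). The smaller of the two tails is summed
    directly (complementing when that is the lower tail) for accuracy.
    """
    ContingencyTable(k, n, K, N)  # validates the margins
    lo = max(0, n + K - N)
    hi = min(n, K)
    if k <= lo:
        return TestResult(1.0, float(k), "upper", "hypergeometric upper tail")
    upper_terms = hi - k + 1
    lower_terms = k - lo  # i in [lo, k-1]
    if upper_terms <= lower_terms:
        logs = [hypergeom_log_pmf(i, n, K, N) for i in range(k, hi + 1)]
        p = math.exp(_logsumexp(logs))
    else:
        logs = [hypergeom_log_pmf(i, n, K, N) for i in range(lo, k)]
        p = 1.0 - math.exp(_logsumexp(logs))
    p = min(max(p, math.exp(hypergeom_log_pmf(hi, n, K, N))), 1.0)
    return TestResult(p, float(k), "upper", "hypergeometric upper tail")


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[ContingencyTable, TestResult]:
    """One-sided enrichment Fisher exact test for the overlap of two gene sets."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValueError(f"set A has elements outside the universe: {sorted(a - u)[:5]}")
    if not b <= u:
        raise ValueError(f"set B has elements outside the universe: {sorted(b - u)[:5]}")
    table = ContingencyTable(len(a & b), len(a), len(b), len(u))
    return table, hypergeom_upper_tail(table.k, table.n, table.K, table.N)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _rank_midranks(pooled: Sequence[float]) -> list[float]:
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # ranks are 1-based
        for t in range(i, j + 1):
            ranks[order[t]] = mid
        i = j + 1
    return ranks


def _u_from_assignment(ranks: Sequence[float], x_idx: Sequence[int], n1: int) -> float:
    r1 = sum(ranks[i] for i in x_idx)
    return r1 - n1 * (n1 + 1) / 2


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null by full enumeration of rank assignments when the combined
    sample size is at most 12 (two-sided p as the permutation probability of
    a U at least as far from n1*n2/2 as observed); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if any(not math.isfinite(v) for v in x + y):
        raise ValueError("samples must be finite")
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = _rank_midranks(pooled)
    u_obs = _u_from_assignment(ranks, range(n1), n1)

    if len(set(pooled)) == 1:
        logger.warning("mann_whitney: all values tied across both samples; p = 1")
        return TestResult(1.0, u_obs, "two-sided", "mann-whitney degenerate")

    mid = n1 * n2 / 2
    if n1 + n2 <= MANN_WHITNEY_EXACT_LIMIT:
        dev_obs = abs(u_obs - mid)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            total += 1
            u = _u_from_assignment(ranks, combo, n1)
            if abs(u - mid) >= dev_obs - 1e-12:
                extreme += 1
        return TestResult(extreme / total, u_obs, "two-sided", "mann-whitney exact")

    # normal approximation with tie and continuity corrections
    n = n1 + n2
    tie_counts: dict[float, int] = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values())
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(1.0, u_obs, "two-sided", "mann-whitney normal")
    z = (abs(u_obs - mid) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2))
    return TestResult(min(p, 1.0), u_obs, "two-sided", "mann-whitney normal")


# ---------------------------------------------------------------------------
# Venn regions
# ---------------------------------------------------------------------------


def venn_counts(
    sets: dict[str, Iterable[str]], universe: Iterable[str]
) -> dict[tuple[str, ...], int]:
    """Count every Venn region of 2 or 3 named sets over a universe.

    Keys are sorted tuples of the set names an element belongs to exactly;
    the empty tuple keys the outside count. Counts sum to |universe|.
    """
    named = {name: set(s) for name, s in sets.items()}
    if not 2 <= len(named) <= 3:
        raise ValueError("venn_counts expects 2 or 3 sets")
    u = set(universe)
    for name, s in named.items():
        if not s <= u:
            raise ValueError(f"set {name!r} has elements outside the universe")
    names = sorted(named)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            counts[combo] = 0
    for el in u:
        membership = tuple(nm for nm in names if el in named[nm])
        counts[membership] += 1
    return counts
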