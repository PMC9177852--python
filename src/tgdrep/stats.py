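"""Exact and asymptotic 2x2 / rank statistics.

The exact machinery here is deliberately self-contained: Fisher's test sums
hypergeometric point probabilities with exact integer arithmetic
(``math.comb``), the chi-square survival function at one degree of freedom
is the closed form ``erfc(sqrt(X2/2))``, and the rank-sum null distribution
is obtained by full enumeration (small samples, ties allowed) or by the
standard counting recursion (tie-free samples).  scipy is used nowhere in
this module so that it can serve as an independent oracle in the test suite.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

EXACT_ENUMERATION_LIMIT = 12   # n+m bound for full permutation enumeration
EXACT_DISTRIBUTION_LIMIT = 40  # n+m bound for the tie-free counting recursion


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]`` (rows = groups, columns = feature +/-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @classmethod
    def from_positives(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Build from per-group positives: ``k1/n1`` vs ``k2/n2``."""
        return cls(k1, n1 - k1, k2, n2 - k2)


@dataclass
class TestResult:
    p_value: float
    statistic: float
    test_name: str
    df: Optional[int] = None


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test by the probability-mass method.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed that of the
    observed table.  Point probabilities are compared as exact integers, so
    the result is reliable for totals well beyond 1000.  The statistic is
    the sample odds ratio ``ad/bc`` (infinite when ``bc = 0`` and ``ad > 0``).
    """
    r1, r2, c1, _ = table.margins
    n = table.n
    if 0 in (r1, r2, c1, table.b + table.d):
        warnings.warn("degenerate margin: Fisher p = 1 by convention")
        return TestResult(1.0, _odds_ratio(table), "fisher_exact", None)
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    w_obs = weights[table.a]
    numer = sum(w for w in weights.values() if w <= w_obs)
    p = float(Fraction(numer, math.comb(n, c1)))
    return TestResult(min(p, 1.0), _odds_ratio(table), "fisher_exact", None)


def _odds_ratio(t: ContingencyTable2x2) -> float:
    if t.b * t.c == 0:
        return math.inf if t.a * t.d > 0 else math.nan
    return (t.a * t.d) / (t.b * t.c)


def chi_square(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction
    by default (``yates=True`` applies the classical correction)."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise ValueError("zero margin: chi-square undefined")
    delta = abs(table.a * table.d - table.b * table.c)
    if yates:
        delta = max(0.0, delta - table.n / 2)
    x2 = table.n * delta * delta / (r1 * r2 * c1 * c2)
    p = math.erfc(math.sqrt(x2 / 2.0))  # chi2 survival function at df=1
    return TestResult(max(min(p, 1.0), 0.0) or 1e-320, x2, "chi_square", 1)


class SelectedTest(str, enum.Enum):
    fisher = "fisher"
    chi2 = "chi2"


def expected_counts(table: ContingencyTable2x2) -> list[float]:
    r1, r2, c1, c2 = table.margins
    n = table.n
    return [r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n]


def select_test(table: ContingencyTable2x2) -> SelectedTest:
    """Fisher when any cell is empty or any expected count is below 5,
    chi-square otherwise."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        return SelectedTest.fisher
    if 0 in (table.a, table.b, table.c, table.d):
        return SelectedTest.fisher
    return SelectedTest.fisher if min(expected_counts(table)) < 5 else SelectedTest.chi2


def run_selected_test(table: ContingencyTable2x2) -> TestResult:
    if select_test(table) is SelectedTest.fisher:
        return fisher_exact_two_sided(table)
    return chi_square(table)


# ---------------------------------------------------------------------------
# Rank-sum (Mann-Whitney) machinery
# ---------------------------------------------------------------------------

def _midranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=values.__getitem__)
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U for x vs y (ties counted half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


@lru_cache(maxsize=128)
def _exact_u_tail_table(n: int, m: int) -> list[Fraction]:
    """``tail[u] = P(U >= u)`` under the tie-free null, by counting subsets.

    ``count[k][u]`` counts k-subsets of ranks ``1..N`` whose U equals ``u``;
    the recursion adds ranks one at a time.
    """
    umax = n * m
    count = [[0] * (umax + 1) for _ in range(n + 1)]
    count[0][0] = 1
    for r in range(1, n + m + 1):
        for k in range(min(r, n), 0, -1):
            # placing rank r in x beats the (r - k) y-values below it... the
            # standard recursion: f(r, k, u) = f(r-1, k, u) + f(r-1, k-1, u-(r-k))
            shift = r - k
            row, prev = count[k], count[k - 1]
            for u in range(umax, shift - 1, -1):
                row[u] += prev[u - shift]
    total = math.comb(n + m, n)
    tail: list[Fraction] = [Fraction(0)] * (umax + 2)
    running = 0
    for u in range(umax, -1, -1):
        running += count[n][u]
        tail[u] = Fraction(running, total)
    return tail


def rank_sum_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided exact p (alternative: x stochastically greater).

    ``p = #(splits with U >= observed U) / C(n+m, n)`` by full enumeration of
    index splits of the pooled sample; with mid-rank U this is a valid
    permutation p-value even in the presence of ties.
    """
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = u_statistic(x, y)
    hits = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in chosen]
        total += 1
        if u_statistic(xs, ys) >= u_obs - 1e-12:
            hits += 1
    return hits / total


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """One-sided rank-sum p-value (x greater), choosing the exact or
    asymptotic path.

    Returns ``(u_statistic, p)``.  Both samples constant and identical give
    ``p = 1`` by convention.  Small pooled samples are enumerated exactly;
    tie-free samples up to ``n+m <= 40`` use the exact null U distribution;
    everything else uses the mid-rank normal approximation with tie
    correction and continuity correction.
    """
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = list(x) + list(y)
    u = u_statistic(x, y)
    if len(set(pooled)) == 1:
        return u, 1.0
    has_ties = len(set(pooled)) < len(pooled)
    if n + m <= EXACT_ENUMERATION_LIMIT:
        return u, rank_sum_exact_p(x, y)
    if not has_ties and n + m <= EXACT_DISTRIBUTION_LIMIT:
        tail = _exact_u_tail_table(n, m)
        return u, float(tail[int(round(u))])
    if has_ties and n + m <= EXACT_ENUMERATION_LIMIT:
        return u, rank_sum_exact_p(x, y)
    # mid-rank normal approximation with tie correction + continuity correction
    ranks = _midranks(pooled)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    nm = n + m
    tie_term = sum(t ** 3 - t for t in ties.values())
    mu = n * m / 2.0
    var = n * m / 12.0 * (nm + 1 - tie_term / (nm * (nm - 1)))
    if var <= 0:
        return u, 1.0
    z = (u - mu - 0.5) / math.sqrt(var)
    p = 0.5 * math.erfc(z / math.sqrt(2.0))
    return u, min(max(p, 1e-320), 1.0)
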