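"""Independent brute-force oracles used by the test suite.

These are deliberately naive: exact integer hypergeometric enumeration for
Fisher tail probabilities, exhaustive rank-assignment enumeration for the
rank-sum test, and direct interval arithmetic for reciprocal overlap. They
share no code with the implementation they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c), computed as an
    exact rational number and converted to float at the end."""
    r1, r2, m = a + b, c + d, a + c
    lo = max(0, m - r2)
    hi = min(r1, m)
    num = sum(comb(r1, k) * comb(r2, m - k) for k in range(max(a, lo), hi + 1))
    den = comb(r1 + r2, m)
    return float(Fraction(num, den))


def exact_rank_sum_greater(x: list[float], y: list[float]) -> float:
    """One-sided (x greater) rank-sum p by enumerating every assignment of
    the pooled values' positions to the x-sample. Tie-free input only."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    n = len(pooled)
    total = 0
    at_least = 0
    for positions in combinations(range(1, n + 1), len(x)):
        total += 1
        if sum(positions) >= observed:
            at_least += 1
    return at_least / total


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))
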