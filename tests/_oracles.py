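"""Independent brute-force oracles used by the tests.

Exact hypergeometric tails by direct pmf enumeration with rational
arithmetic — deliberately independent of scipy and of the package's own
tail computations.
"""

from fractions import Fraction
from math import comb


def hypergeom_pmf(a: int, N: int, R: int, n: int) -> Fraction:
    """P(X = a) drawing n from N with R marked."""
    if a < 0 or a > min(n, R) or n - a > N - R:
        return Fraction(0)
    return Fraction(comb(R, a) * comb(N - R, n - a), comb(N, n))


def upper_tail(A: int, N: int, R: int, n: int) -> float:
    """P(X >= A) by summing the enumerated pmf."""
    return float(sum(hypergeom_pmf(a, N, R, n)
                     for a in range(A, min(n, R) + 1)))


def lower_tail(A: int, N: int, R: int, n: int) -> float:
    """P(X <= A) by summing the enumerated pmf."""
    return float(sum(hypergeom_pmf(a, N, R, n) for a in range(0, A + 1)))
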