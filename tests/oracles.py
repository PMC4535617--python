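"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the Poisson tail is a
500-digit Decimal partial sum of the pmf (1 - cdf cancels catastrophically
once the tail drops below 10^-precision, so the precision must exceed the
smallest tail magnitude probed), and the barcode-collision expectation is
the closed-form birthday count.
"""

from __future__ import annotations

from decimal import Decimal, getcontext


def poisson_tail_decimal(lam: float, n: int) -> float:
    """P(X >= n) for X ~ Poisson(lam) by 500-digit partial summation."""
    if n == 0:
        return 1.0
    getcontext().prec = 500
    dlam = Decimal(repr(lam))
    total = Decimal(0)
    term = Decimal(1)
    for k in range(n):
        if k:
            term *= dlam / k
        total += term
    return float(1 - total * (-dlam).exp())


def expected_distinct(n: int, space: int) -> float:
    """E[# distinct] after n uniform draws from ``space`` values."""
    getcontext().prec = 60
    s = Decimal(space)
    return float(s * (1 - (1 - 1 / s) ** n))
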