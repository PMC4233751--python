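"""Exact counting of Dyck and fate-weighted Motzkin lattice paths.

This is the combinatorial engine behind the clone-size distributions of a
progenitor/differentiated (P/D) birth--death jump chain.  A clone started
from a single proliferating cell gains one cell per division; the number of
proliferating cells performs a lattice walk that moves up (PP division,
probability ``a``), stays flat (PD, probability ``b``) or moves down (DD,
probability ``c``).  Probabilities of reaching a given state are therefore
weighted Motzkin path counts, built here from Dyck-triangle counts.

All pure counts use exact integer arithmetic.  Weighted values propagate the
arithmetic of the supplied fate probabilities: :class:`fractions.Fraction`
inputs stay exact rationals, floats stay floats, and symbolic inputs (e.g.
``sympy`` symbols) stay symbolic, since only ``+``, ``*`` and ``**`` with
integer exponents are used.

Coordinate convention: a path position ``(n, k)`` means ``n`` steps taken and
current height ``k``; heights are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from numbers import Rational
from typing import Any, List, Sequence

__all__ = [
    "FateProbabilities",
    "catalan",
    "dyck_triangle",
    "weighted_motzkin",
    "motzkin_table",
]

#: Tolerance on ``a + b + c = 1`` for floating-point fate probabilities.
FATE_SUM_TOL = 1e-9


def _is_exact(x: Any) -> bool:
    """True when ``x`` participates in exact rational arithmetic."""
    return isinstance(x, Rational)


@dataclass(frozen=True)
class FateProbabilities:
    """Division-outcome probabilities of a proliferating cell.

    Parameters
    ----------
    a : probability of a PP division (two proliferating daughters).
    b : probability of a PD division (one proliferating, one differentiated).
    c : probability of a DD division (two differentiated daughters).

    The three probabilities must lie in [0, 1] and sum to 1 -- exactly when
    given as rationals (``int`` / ``Fraction``), within :data:`FATE_SUM_TOL`
    when given as floats.
    """

    a: Any
    b: Any
    c: Any

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c)
        if any(isinstance(v, complex) for v in vals):
            raise ValueError("fate probabilities must be real numbers")
        try:
            in_range = all(0 <= v <= 1 for v in vals)
        except TypeError:  # symbolic entries: skip numeric validation
            return
        if not in_range:
            raise ValueError(f"fate probabilities must lie in [0, 1], got {vals}")
        total = self.a + self.b + self.c
        if self.is_exact:
            if total != 1:
                raise ValueError(f"a + b + c must equal 1 exactly, got {total}")
        elif abs(total - 1) > FATE_SUM_TOL:
            raise ValueError(f"a + b + c must equal 1 within {FATE_SUM_TOL}, got {total}")

    @property
    def is_exact(self) -> bool:
        """True when all three probabilities are rationals (exact mode)."""
        return all(_is_exact(v) for v in (self.a, self.b, self.c))

    def as_fractions(self) -> "FateProbabilities":
        """Exact-rational copy (floats converted via ``Fraction(float)``)."""
        return FateProbabilities(Fraction(self.a), Fraction(self.b), Fraction(self.c))

    def as_floats(self) -> "FateProbabilities":
        return FateProbabilities(float(self.a), float(self.b), float(self.c))


def catalan(n: int) -> int:
    """The ``n``-th Catalan number, counting Dyck paths of length ``2n``."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return comb(2 * n, n) // (n + 1)


def dyck_triangle(n: int, k: int) -> int:
    """Number of up/down paths from (0, 0) to (n, k) never below the axis.

    Computed by the ballot-number closed form

        D(n, k) = C(n, (n+k)/2) - C(n, (n+k)/2 + 1),

    which satisfies the one-step recurrence
    ``D(n, k) = D(n-1, k-1) + D(n-1, k+1)`` with ``D(2n, 0)`` equal to the
    Catalan number ``C_n`` (verified against the recurrence and exhaustive
    enumeration in the test suite).  Zero when ``n`` and ``k`` have different
    parity or ``k > n``.
    """
    if n < 0 or k < 0:
        raise ValueError(f"n and k must be non-negative, got ({n}, {k})")
    if k > n or (n + k) % 2 == 1:
        return 0
    up = (n + k) // 2
    return comb(n, up) - comb(n, up + 1)


def weighted_motzkin(n: int, k: int, fate: FateProbabilities) -> Any:
    """Weighted Motzkin path value ``m_{n,k}``: probability that the fate walk
    started at height 0 sits at height ``k`` after ``n`` free steps.

    Decomposes each Motzkin path into a Dyck path with ``k + i`` up steps and
    ``i`` down steps interleaved with ``n - k - 2i`` flat steps:

        m_{n,k} = sum_i  C(n, n-k-2i) * D(k+2i, k) * a^(k+i) b^(n-k-2i) c^i.
    """
    if n < 0 or k < 0:
        raise ValueError(f"n and k must be non-negative, got ({n}, {k})")
    if k > n:
        raise ValueError(f"final height k={k} cannot exceed step count n={n}")
    a, b, c = fate.a, fate.b, fate.c
    total = 0
    for i in range((n - k) // 2 + 1):
        flats = n - k - 2 * i
        term = comb(n, flats) * dyck_triangle(k + 2 * i, k)
        total = total + term * a ** (k + i) * b**flats * c**i
    return total


def motzkin_table(n_max: int, fate: FateProbabilities) -> List[Sequence[Any]]:
    """Table of weighted Motzkin values ``m_{n,k}`` for ``0 <= k <= n <= n_max``.

    Filled by the one-step recurrence

        m_{n+1,k} = c * m_{n,k+1} + b * m_{n,k} + a * m_{n,k-1}

    with ``m_{0,0} = 1``.  Row ``n`` of the result has length ``n + 1``; this
    serves as the independent oracle for :func:`weighted_motzkin` (the two are
    distinct computations of the same quantity).
    """
    if n_max < 0:
        raise ValueError(f"n_max must be non-negative, got {n_max}")
    a, b, c = fate.a, fate.b, fate.c
    one = Fraction(1) if fate.is_exact else (a + b + c) ** 0  # 1 of the right type
    zero = one * 0
    rows: List[List[Any]] = [[one]]
    for n in range(n_max):
        prev = rows[-1]

        def at(k: int) -> Any:
            return prev[k] if 0 <= k < len(prev) else zero

        rows.append([c * at(k + 1) + b * at(k) + a * at(k - 1) for k in range(n + 2)])
    return rows
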