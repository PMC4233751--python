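"""Exact mutant-count distributions indexed by colony size.

A colony grows from a single non-mutant cell by a Markovian pure-birth (Yule)
process.  At each division of a non-mutant cell, one daughter is mutant with
probability ``mu1 = 1 - mu0``; mutant cells breed true (no back mutation, no
mutant-specific death).  Conditioning on colony *size* rather than elapsed
time reduces the process to its embedded jump chain: at size ``k`` with ``m``
mutants, a mutant divides next with probability ``m/k`` (``rho*m/(rho*m+n)``
under relative mutant fitness ``rho``), so the distribution of the mutant
count at size ``k`` follows an exact one-step recurrence -- a size-indexed
analogue of the Luria-Delbruck fluctuation distribution.

Support note: the founder is non-mutant and mutants arise only from
non-mutant divisions, so at least one non-mutant lineage remains and the
mutant count at size ``k`` is supported on ``0..k-1``.

Float iterations are vectorized with numpy; supplying ``mu1`` as a
:class:`fractions.Fraction` switches the recurrences to exact rational
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Any, List, Sequence, Union

import numpy as np

__all__ = [
    "MutationModel",
    "MutantCountDistribution",
    "neutral_distribution",
    "neutral_moments",
    "selection_distribution",
]

#: Maximum tolerated probability-mass drift before an error is raised.
NORMALIZATION_TOL = 1e-10


@dataclass(frozen=True)
class MutationModel:
    """Per-division mutation parameters of the growing colony.

    ``mu1``: probability a dividing non-mutant produces one mutant daughter.
    ``rho``: relative mutant fitness (ratio of mutant to non-mutant division
    rates); only this ratio enters any size-indexed distribution.
    ``lambda_``: mean number of distinct mutations per division under the
    Poisson refinement, tied to ``mu1`` by ``mu0 = exp(-lambda_)``.
    """

    mu1: Union[float, Fraction]
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.mu1 <= 1:
            raise ValueError(f"mu1 must lie in [0, 1], got {self.mu1}")
        if self.rho <= 0:
            raise ValueError(f"rho must be positive, got {self.rho}")

    @property
    def mu0(self) -> Union[float, Fraction]:
        return 1 - self.mu1

    @property
    def lambda_(self) -> float:
        if self.mu0 == 0:
            raise ValueError("lambda is undefined for mu0 = 0")
        return -math.log(float(self.mu0))

    @classmethod
    def from_lambda(cls, lambda_: float, rho: float = 1.0) -> "MutationModel":
        if lambda_ < 0:
            raise ValueError(f"lambda must be non-negative, got {lambda_}")
        return cls(mu1=1.0 - math.exp(-lambda_), rho=rho)

    @property
    def is_exact(self) -> bool:
        return isinstance(self.mu1, Rational)


@dataclass(frozen=True)
class MutantCountDistribution:
    """Distribution of the mutant count ``m = 0..k-1`` at colony size ``k``."""

    k: int
    probs: Sequence[Any]
    model: MutationModel

    def __post_init__(self) -> None:
        if len(self.probs) != self.k:
            raise ValueError("probs must have length k (support m = 0..k-1)")
        drift = abs(float(sum(self.probs)) - 1.0)
        if drift > NORMALIZATION_TOL:
            raise ValueError(f"probability mass drifted by {drift:.3e}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.k)

    def mean(self) -> float:
        return float(np.dot(np.asarray(self.probs, dtype=float), self.support))

    def variance(self) -> float:
        p = np.asarray(self.probs, dtype=float)
        mu = float(np.dot(p, self.support))
        return float(np.dot(p, (self.support - mu) ** 2))

    def nonmutant_probs(self) -> np.ndarray:
        """Distribution of the non-mutant count n = k - m, indexed n = 0..k."""
        p = np.zeros(self.k + 1)
        p[1:] = np.asarray(self.probs, dtype=float)[::-1]
        return p


def _neutral_exact(k: int, mu1: Fraction) -> List[Fraction]:
    mu0 = 1 - mu1
    p: List[Fraction] = [Fraction(1)]
    for s in range(1, k):
        new: List[Fraction] = []
        for m in range(s + 1):
            stay = p[m] * Fraction(s - m, s) * mu0 if m < len(p) else Fraction(0)
            up = (
                p[m - 1] * (Fraction(m - 1, s) + Fraction(s - m + 1, s) * mu1)
                if 1 <= m <= len(p)
                else Fraction(0)
            )
            new.append(stay + up)
        p = new
    return p


def neutral_distribution(k: int, model: MutationModel) -> MutantCountDistribution:
    """Exact mutant-count distribution at colony size ``k`` (neutral case).

    Iterates the size-conditioned jump-chain recurrence from a single
    non-mutant cell: at size ``s`` with ``m`` mutants, the next division
    leaves the mutant count unchanged with probability ``((s-m)/s) mu0`` and
    increments it with probability ``m/s + ((s-m)/s) mu1``.  The zero-mutant
    mass is ``mu0^(k-1)`` (all ``k-1`` divisions mutant-free).
    """
    if k < 1:
        raise ValueError(f"colony size k must be >= 1, got {k}")
    if model.rho != 1:
        raise ValueError("neutral_distribution requires rho = 1; use selection_distribution")
    if model.is_exact:
        return MutantCountDistribution(k, _neutral_exact(k, Fraction(model.mu1)), model)
    mu0, mu1 = float(model.mu0), float(model.mu1)
    p = np.array([1.0])
    for s in range(1, k):
        m = np.arange(s + 1)
        new = np.zeros(s + 1)
        new[:s] = p * ((s - m[:s]) / s) * mu0
        new[1:] += p * (m[:s] / s + ((s - m[:s]) / s) * mu1)
        p = new
    return MutantCountDistribution(k, p, model)


@dataclass(frozen=True)
class NonMutantMoments:
    mean_nonmutants: float
    var_nonmutants: float
    mean_mutants: float


def neutral_moments(k: int, model: MutationModel) -> NonMutantMoments:
    """First two moments of the non-mutant count at colony size ``k``.

    The mean has the closed product form ``E^(k) = prod_{j=1..k-1} (j + mu0)/j``
    (each division scales the expected non-mutant share by ``(j + mu0)/(j+1)``
    while the colony grows by ``(j+1)/j``); the variance is accumulated from
    the exact distribution, against which the product form is also validated
    in the tests.
    """
    if k < 1:
        raise ValueError(f"colony size k must be >= 1, got {k}")
    if model.rho != 1:
        raise ValueError("neutral_moments requires rho = 1")
    mu0 = float(model.mu0)
    mean = 1.0
    for j in range(1, k):
        mean *= (j + mu0) / j
    dist = neutral_distribution(k, MutationModel(float(model.mu1)))
    q = dist.nonmutant_probs()
    n = np.arange(k + 1)
    mean_n = float(np.dot(q, n))
    var_n = float(np.dot(q, (n - mean_n) ** 2))
    return NonMutantMoments(mean_nonmutants=mean, var_nonmutants=var_n,
                            mean_mutants=k - mean)


def selection_distribution(k: int, model: MutationModel) -> MutantCountDistribution:
    """Mutant-count distribution at size ``k`` with relative mutant fitness rho.

    Only the rate ratio ``rho = beta_m / beta_n`` enters: competing
    exponential division clocks make the next divider mutant with probability
    ``rho*m / (rho*m + n)``.  One step of the recurrence, from total size
    ``s`` to ``s+1`` (with ``n = s - m`` non-mutants):

        p'[m] = p[m]   * (n / (n + rho*m)) * mu0
              + p[m-1] * ( rho*(m-1) / (rho*(m-1) + n + 1)
                           + ((n+1) / (n + 1 + rho*(m-1))) * mu1 )

    Reduces exactly to :func:`neutral_distribution` at rho = 1, and the
    zero-mutant mass is ``mu0^(k-1)`` independent of rho.
    """
    if k < 1:
        raise ValueError(f"colony size k must be >= 1, got {k}")
    rho = float(model.rho)
    mu0, mu1 = float(model.mu0), float(model.mu1)
    p = np.array([1.0])
    for s in range(1, k):
        m = np.arange(s + 1)
        new = np.zeros(s + 1)
        n_stay = s - m[:s]  # non-mutants before a division that keeps m fixed
        new[:s] = p * (n_stay / (n_stay + rho * m[:s])) * mu0
        m_src = m[:s]  # mutant count before a division that increments it
        n_src = s - m_src
        up = rho * m_src / (rho * m_src + n_src) + (n_src / (n_src + rho * m_src)) * mu1
        new[1:] += p * up
        p = new
    return MutantCountDistribution(k, p, model)
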