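"""Distributions over the mutational subclone structure of a grown colony.

Refines the binary mutant/non-mutant picture: each division may generate new,
individually identifiable mutations (each assumed to arise only once), and a
*clone* is a set of cells sharing an identical combination of mutations -- a
new clone is born at every mutation-producing division.  All distributions
are conditioned on colony size ``k`` under neutral Yule growth, where the
next divider is uniform among the ``j`` cells present (a Polya-urn scheme for
any marked lineage).

Provided, for a colony of ``k`` cells:

* the mutation frequency spectrum -- the number of cells carrying a randomly
  selected mutation (:func:`mutation_frequency_spectrum`), built from the
  conditional kernels ``s^(j,k)_r`` (mutation arising at size ``j``, carried
  by ``r`` of ``k`` cells);
* the number of clones ``C``: ``C - 1 ~ Binomial(k-1, mu1)``
  (:func:`clone_count_distribution`);
* the size of a randomly selected clone (:func:`clone_size_distribution`),
  which coincides entry-for-entry with the frequency spectrum (both follow
  the same Polya recursion) -- kept as an independent implementation so the
  identity is a genuine cross-check;
* the number of distinct mutations carried by a random clone
  (:func:`mutations_per_clone`), under the Poisson refinement where each
  division spawns ``Poisson(lambda)`` mutations with ``mu0 = exp(-lambda)``:
  the founding division contributes a zero-truncated Poisson count and each
  earlier division lies on the founding lineage with probability 1/(r+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .luria_delbruck import MutationModel

__all__ = [
    "SpectrumDistribution",
    "CloneCountDistribution",
    "mutation_kernel",
    "mutation_frequency_spectrum",
    "clone_count_distribution",
    "clone_size_distribution",
    "mutations_per_clone",
]


@dataclass(frozen=True)
class SpectrumDistribution:
    """Probability a random mutation is carried by ``r = 1..k-1`` of k cells."""

    k: int
    probs: Sequence[Any]

    def __post_init__(self) -> None:
        if len(self.probs) != self.k - 1:
            raise ValueError("probs must have length k - 1 (support r = 1..k-1)")

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.k)

    def as_dict(self) -> Dict[int, Any]:
        return dict(zip(range(1, self.k), self.probs))


def mutation_kernel(j: int, k: int, exact: bool = False) -> Sequence[Any]:
    """Conditional carrier-count kernel ``s^(j,k)_r`` for ``r = 1..k-j+1``.

    Probability that a mutation arising in one cell when the colony has ``j``
    cells is carried by ``r`` cells at size ``k``.  Polya one-step recurrence
    in the colony size ``K``:

        s^(j,K)_r = s^(j,K-1)_{r-1} * (r-1)/(K-1) + s^(j,K-1)_r * (K-1-r)/(K-1)

    from ``s^(j,j)_1 = 1``.
    """
    if j < 2 or k < j:
        raise ValueError(f"need 2 <= j <= k, got j={j}, k={k}")
    if exact:
        s: List[Any] = [Fraction(1)]
        for size in range(j + 1, k + 1):
            prev, d = s, size - 1
            s = []
            for r in range(1, len(prev) + 2):
                grow = prev[r - 2] * Fraction(r - 1, d) if 2 <= r <= len(prev) + 1 else 0
                stay = prev[r - 1] * Fraction(d - r, d) if r <= len(prev) else 0
                s.append(grow + stay)
        return s
    s_arr = np.array([1.0])
    for size in range(j + 1, k + 1):
        d = size - 1
        r = np.arange(1, len(s_arr) + 2)
        new = np.zeros(len(s_arr) + 1)
        new[1:] = s_arr * (r[1:] - 1) / d
        new[:-1] += s_arr * (d - r[:-1]) / d
        s_arr = new
    return s_arr


def mutation_frequency_spectrum(k: int, exact: bool = False) -> SpectrumDistribution:
    """Distribution of the carrier count of a randomly selected mutation.

    A random mutation arises at any of the ``k - 1`` divisions with equal
    probability; averaging the conditional kernels gives

        p^(k)_r = (1/(k-1)) * sum_{j=2}^{k-r+1} s^(j,k)_r.
    """
    if k < 2:
        raise ValueError(f"colony size k must be >= 2, got {k}")
    if exact:
        probs: List[Any] = [Fraction(0)] * (k - 1)
        for j in range(2, k + 1):
            for idx, val in enumerate(mutation_kernel(j, k, exact=True)):
                probs[idx] += val
        return SpectrumDistribution(k, [p / (k - 1) for p in probs])
    acc = np.zeros(k - 1)
    for j in range(2, k + 1):
        kern = np.asarray(mutation_kernel(j, k))
        acc[: len(kern)] += kern
    return SpectrumDistribution(k, acc / (k - 1))


@dataclass(frozen=True)
class CloneCountDistribution:
    """Distribution of the number of clones C = 1..k in a colony of k cells."""

    k: int
    probs: np.ndarray
    model: MutationModel

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, self.k + 1)

    def mean(self) -> float:
        return float(np.dot(self.probs, self.support))


def clone_count_distribution(k: int, model: MutationModel) -> CloneCountDistribution:
    """Number of clones: one more than the number of mutation-producing
    divisions, so ``C - 1 ~ Binomial(k-1, mu1)``."""
    if k < 1:
        raise ValueError(f"colony size k must be >= 1, got {k}")
    probs = stats.binom.pmf(np.arange(k), k - 1, float(model.mu1))
    return CloneCountDistribution(k, probs, model)


def clone_size_distribution(k: int, exact: bool = False) -> SpectrumDistribution:
    """Size distribution of a randomly selected clone in a colony of k cells.

    A clone founded at division ``i`` starts as one cell among ``i + 1``;
    while the colony grows from ``i + 1`` to ``k`` cells, the next divider is
    clonal with probability ``n / (current size)``.  Averaging uniformly over
    the founding division ``i = 1..k-1`` gives the distribution.  Implemented
    directly from this construction (independently of
    :func:`mutation_frequency_spectrum`, to which it is identical -- the same
    Polya recursion with ``j = i + 1``).
    """
    if k < 2:
        raise ValueError(f"colony size k must be >= 2, got {k}")
    if exact:
        total: List[Any] = [Fraction(0)] * (k - 1)
        for i in range(1, k):
            cl: List[Any] = [Fraction(1)]  # one clonal cell at colony size i+1
            for size in range(i + 1, k):  # a division occurs at colony size `size`
                new = [Fraction(0)] * (len(cl) + 1)
                for idx, p in enumerate(cl):
                    n = idx + 1
                    new[idx + 1] += p * Fraction(n, size)
                    new[idx] += p * Fraction(size - n, size)
                cl = new
            for idx, p in enumerate(cl):
                total[idx] += p
        return SpectrumDistribution(k, [p / (k - 1) for p in total])
    total_arr = np.zeros(k - 1)
    for i in range(1, k):
        cl_arr = np.array([1.0])
        for size in range(i + 1, k):
            n = np.arange(1, len(cl_arr) + 1)
            new = np.zeros(len(cl_arr) + 1)
            new[1:] = cl_arr * n / size
            new[:-1] += cl_arr * (size - n) / size
            cl_arr = new
        total_arr[: len(cl_arr)] += cl_arr
    return SpectrumDistribution(k, total_arr / (k - 1))


@dataclass(frozen=True)
class MutationsPerCloneDistribution:
    """Distribution of the mutation count of a random clone (support >= 1)."""

    k: int
    probs: np.ndarray  # probs[i] = P(count = i + 1)
    model: MutationModel

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, len(self.probs) + 1)


def _series_tail_length(lam: float, k: int) -> int:
    # generous truncation: mean count is ~1 + lam * H_k; pad by Poisson-ish tail
    mean = 1.0 + lam * (math.log(k + 1) + 1.0)
    return max(32, int(mean + 12.0 * math.sqrt(mean) + 10))


def mutations_per_clone(
    k: int,
    model: MutationModel,
    mode: str = "pgf",
    seed: Optional[int] = None,
    n_samples: int = 100_000,
):
    """Number of distinct mutations carried by a randomly selected clone.

    The clone is founded at division ``i``, uniform on ``1..k-1``.  Its count
    is ``Z + sum_{r=1}^{i-1} X_r N_r`` with ``Z`` the founding division's
    mutation count (Poisson(lambda) conditioned >= 1, since a clone exists
    only if the division produced a mutation), ``X_r ~ Bernoulli(1/(r+1))``
    the event that division ``r`` lies on the founding lineage, and
    ``N_r ~ Poisson(lambda)`` i.i.d.

    ``mode="pgf"`` multiplies the factor generating functions
    ``r/(r+1) + e^{lambda(s-1)}/(r+1)`` as truncated power series and returns
    the probabilities; ``mode="sample"`` draws Monte-Carlo samples and
    returns an integer array.
    """
    if k < 2:
        raise ValueError(f"colony size k must be >= 2, got {k}")
    mu0 = float(model.mu0)
    if mu0 <= 0.0 or mu0 >= 1.0:
        raise ValueError("mutations_per_clone requires mu0 strictly inside (0, 1)")
    lam = model.lambda_
    if mode == "pgf":
        L = _series_tail_length(lam, k)
        pois = stats.poisson.pmf(np.arange(L), lam)
        # zero-truncated Poisson for the founding division
        trunc = pois.copy()
        trunc[0] = 0.0
        trunc /= 1.0 - pois[0]
        # prefix products of the lineage factors, averaged over founding division
        avg = np.zeros(L)
        prefix = np.zeros(L)
        prefix[0] = 1.0  # empty product (founding division i = 1)
        for i in range(1, k):
            avg += prefix
            if i < k - 1:
                factor = pois / (i + 1)
                factor[0] += i / (i + 1)
                prefix = np.convolve(prefix, factor)[:L]
        avg /= k - 1
        probs = np.convolve(trunc, avg)[:L]
        tail = 1.0 - probs.sum()
        if tail > 1e-9:
            raise RuntimeError(f"series truncation lost {tail:.2e} probability mass")
        return MutationsPerCloneDistribution(k, probs[1:], model)
    if mode == "sample":
        rng = np.random.default_rng(seed)
        i = rng.integers(1, k, size=n_samples)
        # zero-truncated Poisson by inverse transform
        pois_cdf = stats.poisson.cdf(np.arange(_series_tail_length(lam, k)), lam)
        u = stats.poisson.pmf(0, lam) + rng.random(n_samples) * (1.0 - stats.poisson.pmf(0, lam))
        z = np.searchsorted(pois_cdf, u)
        counts = z.astype(np.int64)
        for r in range(1, k - 1):
            active = i > r
            on_lineage = rng.random(n_samples) < 1.0 / (r + 1)
            counts += rng.poisson(lam, n_samples) * (active & on_lineage)
        return counts
    raise ValueError(f"mode must be 'pgf' or 'sample', got {mode!r}")
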