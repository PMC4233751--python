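"""Independent brute-force oracles used by the test suite.

Everything here enumerates explicit step sequences or labelled lineage
histories; none of it shares code with the recurrences under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from typing import Dict, List, Tuple

import numpy as np


def enumerate_dyck_paths(n: int, k: int) -> int:
    """Count up/down paths (0,0) -> (n,k) staying >= 0 by full enumeration."""
    steps = np.array(list(product((1, -1), repeat=n)), dtype=np.int8)
    if steps.size == 0:  # n == 0
        return int(k == 0)
    heights = np.cumsum(steps, axis=1)
    ok = (heights.min(axis=1) >= 0) & (heights[:, -1] == k)
    return int(ok.sum())


def enumerate_weighted_motzkin(n: int, k: int, a, b, c):
    """Weighted Motzkin value m_{n,k} by enumeration of all 3^n sequences."""
    total = 0
    for steps in product((1, 0, -1), repeat=n):
        h = 0
        ok = True
        for s in steps:
            h += s
            if h < 0:
                ok = False
                break
        if not ok or h != k:
            continue
        ups = steps.count(1)
        downs = steps.count(-1)
        total = total + a**ups * b ** (n - ups - downs) * c**downs
    return total


def enumerate_weighted_motzkin_fast(n: int, a: float, b: float, c: float) -> np.ndarray:
    """Vectorized float enumeration of all 3^n step sequences; returns the
    weighted path totals for every final height k = 0..n at once."""
    m = 3**n
    codes = np.arange(m, dtype=np.int64)
    steps = np.empty((m, n), dtype=np.int8)
    for j in range(n):
        steps[:, j] = (codes % 3).astype(np.int8) - 1
        codes //= 3
    heights = np.cumsum(steps, axis=1, dtype=np.int8)
    valid = heights.min(axis=1) >= 0
    final = heights[:, -1].astype(np.int64)
    ups = (steps == 1).sum(axis=1)
    downs = (steps == -1).sum(axis=1)
    w = a**ups * b ** (n - ups - downs) * c**downs
    out = np.zeros(n + 1)
    np.add.at(out, final[valid], w[valid])
    return out


def enumerate_fate_paths(n_steps: int, k_start: int, k_end: int) -> List[Tuple[int, int, int]]:
    """All jump-chain paths of the fate walk from height ``k_start`` to
    ``k_end`` in ``n_steps`` steps that never touch height 0; returns the
    (ups, flats, downs) composition of each admissible path."""
    out = []
    for steps in product((1, 0, -1), repeat=n_steps):
        h = k_start
        ok = True
        for s in steps:
            h += s
            if h <= 0:
                ok = False
                break
        if ok and h == k_end:
            out.append((steps.count(1), steps.count(0), steps.count(-1)))
    return out


def enumerate_mutation_spectrum(k: int) -> Dict[int, Fraction]:
    """Carrier-count distribution of a random mutation in a k-cell colony.

    Enumerates labelled histories explicitly: a colony of ``size`` cells
    divides by choosing each cell with probability 1/size (the chosen cell's
    daughter is appended); the mutation arises at a uniformly chosen division
    and is inherited by both daughters of any carrier.  Exact Fractions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    dist: Dict[int, Fraction] = {}

    def advance(carriers: frozenset, size: int, weight: Fraction) -> None:
        if size == k:
            r = len(carriers)
            dist[r] = dist.get(r, Fraction(0)) + weight
            return
        for cell in range(size):
            w = weight / size
            new_carriers = carriers | {size} if cell in carriers else carriers
            advance(new_carriers, size + 1, w)

    # the mutation arises at the division taking the colony from j-1 to j
    # cells (j = 2..k), with equal probability 1/(k-1); it lands in the new
    # daughter cell, index j-1 in the labelling
    for j in range(2, k + 1):
        # enumerate the divisions before the mutation arises (they only set
        # the stage; carriers are determined from the mutation onward)
        advance(frozenset({j - 1}), j, Fraction(1, k - 1))
    return dist


def enumerate_mutant_counts(k: int, mu1: Fraction) -> Dict[int, Fraction]:
    """Mutant-count distribution at colony size k by enumerating labelled
    histories: each division picks a uniform cell; a mutant divider yields a
    mutant daughter; a non-mutant divider yields a mutant daughter with
    probability mu1 (branching on both outcomes).  Exact Fractions."""
    mu0 = 1 - mu1
    dist: Dict[int, Fraction] = {}

    def advance(genotypes: Tuple[bool, ...], weight: Fraction) -> None:
        size = len(genotypes)
        if size == k:
            m = sum(genotypes)
            dist[m] = dist.get(m, Fraction(0)) + weight
            return
        for cell, is_mut in enumerate(genotypes):
            w = weight / size
            if is_mut:
                advance(genotypes + (True,), w)
            else:
                if mu1 > 0:
                    advance(genotypes + (True,), w * mu1)
                if mu0 > 0:
                    advance(genotypes + (False,), w * mu0)

    advance((False,), Fraction(1))
    return dist
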