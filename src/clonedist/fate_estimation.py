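"""Estimating division-fate probabilities from fully differentiated clone counts.

At late observation times, small clones that have stopped growing consist
entirely of differentiated cells, and their size distribution is the ruin
series ``{P_{n,0}} = {c, bc, c(b^2 + ac), ...}``.  Consecutive ratios of the
observed counts therefore identify the fate parameters without observing any
individual division:

    N3 / N2  estimates  P_{3,0} / P_{2,0} = b
    N4 / N3  estimates  P_{4,0} / P_{3,0} = (b^2 + ac) / b

giving ``b_hat = N3/N2`` and ``ac_hat = b_hat * (N4/N3) - b_hat^2``.  With
``a + c = 1 - b_hat``, the pair (a, c) are the two roots of
``x^2 - (1 - b_hat) x + ac_hat = 0``.  The counts alone cannot say which root
is ``a``: the quadratic is symmetric in (a, c), so the assignment is a policy
choice informed by side information (e.g. the presence of still-expanding
clones indicates a > c).

Also provided: a multinomial maximum-likelihood extension using all sizes up
to ``n_max`` (a generalization beyond the three-ratio method), and a
multinomial bootstrap for percentile confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import optimize

from .homeostasis import ruin_probabilities
from .path_combinatorics import FateProbabilities

__all__ = [
    "CloneSizeCounts",
    "FateEstimate",
    "estimate_fate_ratio",
    "estimate_fate_mle",
    "bootstrap_fate",
]


@dataclass(frozen=True)
class CloneSizeCounts:
    """Observed counts of fully differentiated clones by size (sizes >= 2)."""

    counts: Mapping[int, int]
    total_clones: Optional[int] = None  # whole-experiment clone total (metadata only)
    n_censored: Optional[int] = None  # still-proliferating clones excluded

    def __post_init__(self) -> None:
        for size, count in self.counts.items():
            if int(size) != size or size < 2:
                raise ValueError(f"clone sizes must be integers >= 2, got {size}")
            if int(count) != count or count < 0:
                raise ValueError(f"counts must be non-negative integers, got {count}")

    def __getitem__(self, size: int) -> int:
        return int(self.counts.get(size, 0))

    @property
    def n_observed(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class FateEstimate:
    """Result of a fate-probability estimation.

    ``fate`` is None when the moment conditions are infeasible (see
    ``diagnostics``); infeasibility is a flagged outcome, not an exception.
    """

    fate: Optional[FateProbabilities]
    b_hat: float
    ac_hat: float
    root_policy: str = "a_greater"
    feasible: bool = True
    diagnostics: str = ""
    ci: Optional[Dict[str, Tuple[float, float]]] = None
    log_likelihood: Optional[float] = None
    n_infeasible_replicates: Optional[int] = None
    b_hat_exact: Optional[Fraction] = field(default=None, repr=False)
    ac_hat_exact: Optional[Fraction] = field(default=None, repr=False)


_POLICIES = ("a_greater", "c_greater")


def estimate_fate_ratio(
    counts: CloneSizeCounts, root_policy: str = "a_greater"
) -> FateEstimate:
    """Ratio estimator of (a, b, c) from the counts of 2-, 3- and 4-cell clones.

    Moment identities: ``b = N3/N2`` and ``ac = b (N4/N3) - b^2``; (a, c) are
    the roots of ``x^2 - (1 - b) x + ac``, assigned by ``root_policy``.
    Intermediate moments are carried as exact rationals; only the final root
    extraction uses floating point.
    """
    if root_policy not in _POLICIES:
        raise ValueError(f"root_policy must be one of {_POLICIES}")
    n2, n3, n4 = counts[2], counts[3], counts[4]
    if min(n2, n3, n4) <= 0:
        raise ValueError("sizes 2, 3 and 4 must all have positive counts")
    b_hat = Fraction(n3, n2)
    ac_hat = b_hat * Fraction(n4, n3) - b_hat * b_hat

    def infeasible(reason: str) -> FateEstimate:
        return FateEstimate(
            fate=None,
            b_hat=float(b_hat),
            ac_hat=float(ac_hat),
            root_policy=root_policy,
            feasible=False,
            diagnostics=reason,
            b_hat_exact=b_hat,
            ac_hat_exact=ac_hat,
        )

    if b_hat >= 1:
        return infeasible(f"b_hat = {float(b_hat):.4g} >= 1")
    if ac_hat < 0:
        return infeasible(f"ac_hat = {float(ac_hat):.4g} < 0")
    disc = (1 - b_hat) ** 2 - 4 * ac_hat
    if disc < 0:
        return infeasible(f"discriminant {float(disc):.4g} < 0: no real roots")
    root = math.sqrt(disc)
    s = float(1 - b_hat)
    hi, lo = (s + root) / 2, (s - root) / 2
    a, c = (hi, lo) if root_policy == "a_greater" else (lo, hi)
    fate = FateProbabilities(a, 1.0 - a - c, c)
    return FateEstimate(
        fate=fate,
        b_hat=float(b_hat),
        ac_hat=float(ac_hat),
        root_policy=root_policy,
        feasible=True,
        b_hat_exact=b_hat,
        ac_hat_exact=ac_hat,
    )


def _ruin_pmf(a: float, c: float, n_max: int) -> np.ndarray:
    fate = FateProbabilities(a, 1.0 - a - c, c)
    probs = np.asarray(ruin_probabilities(n_max, fate).probs, dtype=float)
    total = probs.sum()
    if total <= 0:
        return np.full(n_max - 1, np.nan)
    return probs / total


def estimate_fate_mle(
    counts: CloneSizeCounts, n_max: int, root_policy: str = "a_greater"
) -> FateEstimate:
    """Multinomial maximum-likelihood fate estimate using sizes 2..n_max.

    Maximizes the likelihood of the observed size counts under the truncated
    ruin distribution ``P_{n,0} / sum_{j=2..n_max} P_{j,0}`` over the
    probability simplex.  This uses information the three-ratio method
    ignores (all sizes up to ``n_max``) and is an extension of, not a
    substitute for, the ratio estimator.  The likelihood is symmetric in
    (a, c); the reported orientation follows ``root_policy``.
    """
    if n_max < 4:
        raise ValueError(f"n_max must be >= 4, got {n_max}")
    if root_policy not in _POLICIES:
        raise ValueError(f"root_policy must be one of {_POLICIES}")
    sizes = np.arange(2, n_max + 1)
    obs = np.array([counts[int(n)] for n in sizes], dtype=float)
    if obs.sum() <= 0:
        raise ValueError("no observed counts within 2..n_max")
    extra = [n for n in counts.counts if n > n_max]
    if extra:
        raise ValueError(f"counts at sizes {sorted(extra)} exceed n_max={n_max}")

    def nll(x: np.ndarray) -> float:
        a, c = x
        if a < 0 or c < 0 or a + c >= 1:
            return np.inf
        pmf = _ruin_pmf(a, c, n_max)
        if not np.all(np.isfinite(pmf)) or np.any(pmf[obs > 0] <= 0):
            return np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(obs > 0, obs * np.log(pmf), 0.0)
        return -float(ll.sum())

    best = None
    fatol = 1e-9 * max(1.0, float(obs.sum()))  # NLL scales with the count total
    for start in ((0.3, 0.3), (0.1, 0.5), (0.45, 0.2)):
        res = optimize.minimize(nll, np.array(start), method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": fatol, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    a, c = float(best.x[0]), float(best.x[1])
    if root_policy == "a_greater" and a < c:
        a, c = c, a
    if root_policy == "c_greater" and c < a:
        a, c = c, a
    b = 1.0 - a - c
    boundary = min(a, b, c) < 1e-6
    diagnostics = ""
    if not best.success:
        diagnostics = f"optimizer did not converge: {best.message}"
    if boundary:
        diagnostics = (diagnostics + "; " if diagnostics else "") + \
            "solution on the simplex boundary"
    fate = FateProbabilities(max(a, 0.0), b, max(c, 0.0))
    return FateEstimate(
        fate=fate,
        b_hat=b,
        ac_hat=a * c,
        root_policy=root_policy,
        feasible=best.success and not boundary,
        diagnostics=diagnostics,
        log_likelihood=-float(best.fun),
    )


def bootstrap_fate(
    counts: CloneSizeCounts,
    replicates: int = 2000,
    seed: int = 0,
    root_policy: str = "a_greater",
) -> FateEstimate:
    """Multinomial bootstrap of the ratio estimator.

    Resamples the observed count vector (multinomial over size classes),
    re-runs :func:`estimate_fate_ratio` per replicate, and reports percentile
    (2.5%, 97.5%) intervals for a, b, c, b_hat and ac_hat.  Replicates whose
    moment conditions are infeasible are counted and excluded.
    """
    if replicates < 100:
        raise ValueError(f"replicates must be >= 100, got {replicates}")
    point = estimate_fate_ratio(counts, root_policy)
    sizes = sorted(counts.counts)
    obs = np.array([counts[s] for s in sizes], dtype=float)
    total = int(obs.sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total, obs / obs.sum(), size=replicates)
    kept: Dict[str, list] = {k: [] for k in ("a", "b", "c", "b_hat", "ac_hat")}
    n_bad = 0
    for row in draws:
        resampled = dict(zip(sizes, (int(v) for v in row)))
        if min(resampled.get(2, 0), resampled.get(3, 0), resampled.get(4, 0)) <= 0:
            n_bad += 1
            continue
        est = estimate_fate_ratio(CloneSizeCounts(resampled), root_policy)
        if not est.feasible:
            n_bad += 1
            continue
        assert est.fate is not None
        kept["a"].append(est.fate.a)
        kept["b"].append(est.fate.b)
        kept["c"].append(est.fate.c)
        kept["b_hat"].append(est.b_hat)
        kept["ac_hat"].append(est.ac_hat)
    if n_bad > replicates / 2:
        warnings.warn(
            f"{n_bad}/{replicates} bootstrap replicates were infeasible; "
            "percentile intervals may be unreliable"
        )
    ci = {
        k: tuple(np.percentile(v, [2.5, 97.5])) if v else (math.nan, math.nan)
        for k, v in kept.items()
    }
    return FateEstimate(
        fate=point.fate,
        b_hat=point.b_hat,
        ac_hat=point.ac_hat,
        root_policy=root_policy,
        feasible=point.feasible,
        diagnostics=point.diagnostics,
        ci=ci,  # type: ignore[arg-type]
        n_infeasible_replicates=n_bad,
        b_hat_exact=point.b_hat_exact,
        ac_hat_exact=point.ac_hat_exact,
    )
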