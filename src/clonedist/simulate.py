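"""Stochastic simulators: jump-chain and continuous-time oracles.

These simulators are the package's independent check on every exact
distribution: the homeostatic progenitor/differentiated walk, the growing
colony with mutation (with or without selection), genotype-tracked growth for
subclone structure, and a synthetic generator of fully-differentiated clone
count tables for the fate estimator.

Time-independence is the organizing principle: the continuous-time simulator
draws exponential holding times with rate proportional to the number of
dividing cells, but its *embedded* chain -- the sequence of states at
division events -- is distributed identically to the discrete jump chain.
Both modes are provided so that this equivalence is something the test suite
measures rather than assumes.

Reproducibility: every run consumes a single ``numpy.random.default_rng``
seeded from the config; identical config + seed gives identical results.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .fate_estimation import CloneSizeCounts
from .luria_delbruck import MutationModel
from .path_combinatorics import FateProbabilities

__all__ = [
    "SimulationConfig",
    "HomeostasisResult",
    "GrowthResult",
    "GenotypeRecord",
    "simulate_homeostasis",
    "simulate_mutation_growth",
    "generate_count_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of simulation parameters.

    ``stop_size`` stops a replicate when the clone/colony reaches that total
    size; homeostasis replicates also stop at full differentiation (k = 0) or
    after ``max_divisions`` divisions.  ``beta_n``/``beta_m`` are division
    rates per cell per unit time for the continuous-time mode; for growth
    runs only their ratio (the relative fitness rho) matters and must agree
    with ``model.rho``.
    """

    fate: Optional[FateProbabilities] = None
    model: Optional[MutationModel] = None
    beta_n: float = 1.0
    beta_m: Optional[float] = None
    stop_size: Optional[int] = None
    max_divisions: int = 10_000
    replicates: int = 1
    seed: int = 0
    time_mode: str = "jump"  # "jump" | "continuous"
    genotype: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.time_mode not in ("jump", "continuous"):
            raise ValueError("time_mode must be 'jump' or 'continuous'")
        if self.model is not None and self.beta_m is not None:
            rho = self.beta_m / self.beta_n
            if abs(rho - float(self.model.rho)) > 1e-12:
                raise ValueError(
                    f"beta_m/beta_n = {rho} conflicts with model.rho = {self.model.rho}"
                )


@dataclass(frozen=True)
class HomeostasisResult:
    """Per-replicate final states of homeostatic clone simulations."""

    final_n: np.ndarray  # total cells at stop
    final_k: np.ndarray  # proliferating cells at stop (0 if absorbed)
    absorbed: np.ndarray  # True where the clone fully differentiated
    divisions: np.ndarray
    final_time: Optional[np.ndarray] = None  # continuous mode only
    config: Optional[SimulationConfig] = None

    @property
    def absorbed_sizes(self) -> np.ndarray:
        return self.final_n[self.absorbed]


def simulate_homeostasis(config: SimulationConfig) -> HomeostasisResult:
    """Simulate replicate clones of the P/D fate process from one P cell.

    Jump-chain mode draws division outcomes i.i.d. (a, b, c) -- which cell
    divides is irrelevant to the counts.  Continuous-time mode additionally
    draws exponential waiting times with rate ``beta_n * k``; the embedded
    chain is identical in law.  Replicates that fully differentiate before
    reaching ``stop_size`` are recorded as absorbed (not an error).
    """
    fate = config.fate
    if fate is None:
        raise ValueError("config.fate is required")
    a, b = float(fate.a), float(fate.b)
    rng = np.random.default_rng(config.seed)
    reps = config.replicates
    n = np.ones(reps, dtype=np.int64)
    k = np.ones(reps, dtype=np.int64)
    divisions = np.zeros(reps, dtype=np.int64)
    t = np.zeros(reps) if config.time_mode == "continuous" else None
    active = np.ones(reps, dtype=bool)
    if config.stop_size is not None and config.stop_size <= 1:
        active[:] = False
    steps = 0
    while active.any() and steps < config.max_divisions:
        idx = np.nonzero(active)[0]
        if t is not None:
            t[idx] += rng.exponential(1.0 / (config.beta_n * k[idx]))
        u = rng.random(idx.size)
        dk = np.where(u < a, 1, np.where(u < a + b, 0, -1)).astype(np.int64)
        k[idx] += dk
        n[idx] += 1
        divisions[idx] += 1
        newly_absorbed = idx[k[idx] == 0]
        active[newly_absorbed] = False
        if config.stop_size is not None:
            active[idx[n[idx] >= config.stop_size]] = False
        steps += 1
    return HomeostasisResult(
        final_n=n, final_k=k, absorbed=(k == 0), divisions=divisions,
        final_time=t, config=config,
    )


@dataclass(frozen=True)
class GenotypeRecord:
    """Subclone structure of one genotype-tracked colony.

    ``lineage_clone_sizes`` lists the founder's unmutated lineage first,
    followed by mutant clones in order of founding; ``mutations_per_lineage_clone``
    covers the mutant clones only (the unmutated lineage carries none).
    """

    mutation_cell_counts: Tuple[int, ...]  # cells carrying each mutation
    lineage_clone_sizes: Tuple[int, ...]  # founding-lineage clone definition
    genotype_clone_sizes: Tuple[int, ...]  # exact-genotype clone definition
    mutations_per_lineage_clone: Tuple[int, ...]  # distinct mutations at founding
    n_clones: int  # 1 + number of mutation-producing divisions


@dataclass(frozen=True)
class GrowthResult:
    """Per-replicate outcomes of growing-colony mutation simulations."""

    k: int
    mutant_counts: np.ndarray
    genotype_records: Optional[List[GenotypeRecord]] = None
    config: Optional[SimulationConfig] = None


def _simulate_genotypes(k: int, lam: float, reps: int, rng: np.random.Generator
                        ) -> List[GenotypeRecord]:
    records: List[GenotypeRecord] = []
    for _ in range(reps):
        genotypes: List[Tuple[int, ...]] = [()]
        clone_ids: List[int] = [0]
        founding_muts: List[int] = [0]  # mutation count of each clone's founder
        mut_counts: Dict[int, int] = {}
        next_mut = 0
        next_clone = 1
        z_draws = rng.poisson(lam, k - 1)
        u_draws = rng.random(k - 1)
        for step in range(k - 1):
            size = step + 1
            idx = int(u_draws[step] * size)
            g = genotypes[idx]
            for mid in g:
                mut_counts[mid] += 1
            z = int(z_draws[step])
            if z > 0:
                new_ids = tuple(range(next_mut, next_mut + z))
                next_mut += z
                for mid in new_ids:
                    mut_counts[mid] = 1
                genotypes.append(g + new_ids)
                clone_ids.append(next_clone)
                founding_muts.append(len(g) + z)
                next_clone += 1
            else:
                genotypes.append(g)
                clone_ids.append(clone_ids[idx])
        lineage_sizes = tuple(Counter(clone_ids).values())
        genotype_sizes = tuple(Counter(genotypes).values())
        records.append(
            GenotypeRecord(
                mutation_cell_counts=tuple(mut_counts.values()),
                lineage_clone_sizes=lineage_sizes,
                genotype_clone_sizes=genotype_sizes,
                mutations_per_lineage_clone=tuple(founding_muts[1:]),
                n_clones=next_clone,
            )
        )
    return records


def simulate_mutation_growth(config: SimulationConfig) -> GrowthResult:
    """Grow replicate colonies to ``stop_size`` cells under mutation.

    Vectorized mutant-count mode: at total size ``s`` with ``m`` mutants, the
    divider is mutant with probability ``rho*m / (rho*m + (s - m))``; a
    dividing non-mutant spawns a mutant daughter with probability ``mu1``.

    Genotype mode (neutral growth only) tracks unique mutation labels: each
    division attaches ``Poisson(lambda)`` fresh labels to one daughter,
    founding a new clone.  Records per-mutation cell counts and clone
    partitions under both the founding-lineage definition (all descendants of
    the founding cell) and the exact-genotype definition (cells with an
    identical mutation set).
    """
    model = config.model
    if model is None:
        raise ValueError("config.model is required")
    if config.stop_size is None or config.stop_size < 1:
        raise ValueError("growth runs require stop_size >= 1")
    k = config.stop_size
    rng = np.random.default_rng(config.seed)
    reps = config.replicates
    if config.genotype:
        if float(model.rho) != 1.0:
            raise ValueError("genotype mode supports neutral growth (rho = 1) only")
        records = _simulate_genotypes(k, model.lambda_, reps, rng)
        # mutant cells = cells with a non-empty mutation set = k - size of the
        # founder's own (label-free) lineage clone, recorded first.
        mutants = np.array(
            [k - rec.lineage_clone_sizes[0] for rec in records], dtype=np.int64
        )
        return GrowthResult(k=k, mutant_counts=mutants, genotype_records=records,
                            config=config)
    rho = float(model.rho)
    mu1 = float(model.mu1)
    m = np.zeros(reps, dtype=np.int64)
    for s in range(1, k):
        n_non = s - m
        p_mut_div = rho * m / (rho * m + n_non)
        u1 = rng.random(reps)
        u2 = rng.random(reps)
        mutant_divides = u1 < p_mut_div
        new_mutant = mutant_divides | (~mutant_divides & (u2 < mu1))
        m += new_mutant
    return GrowthResult(k=k, mutant_counts=m, config=config)


def generate_count_fixture(
    fate: FateProbabilities,
    n_clones: int,
    max_size: int = 20,
    seed: int = 0,
) -> CloneSizeCounts:
    """Synthetic table of fully differentiated clone-size counts.

    Simulates ``n_clones`` single-P-cell clones to absorption; clones still
    proliferating at ``max_size`` are censored and excluded, mimicking the
    observational exclusion of still-expanding clones.  The censored count is
    reported on the result.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    config = SimulationConfig(
        fate=fate, stop_size=max_size, max_divisions=max_size + 1,
        replicates=n_clones, seed=seed,
    )
    result = simulate_homeostasis(config)
    sizes, freq = np.unique(result.absorbed_sizes, return_counts=True)
    counts = {int(s): int(f) for s, f in zip(sizes, freq)}
    n_censored = int(n_clones - result.absorbed.sum())
    return CloneSizeCounts(counts=counts, total_clones=n_clones, n_censored=n_censored)
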