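# clonedist

Exact, size-indexed distributions for clonal dynamics: progenitor fate in
homeostatic epithelium, gambler's-ruin clone sizes, and Luria–Delbrück-type
mutant and subclone distributions in growing colonies.

## The problem

Lineage-tracing, clonal culture and deep-sequencing experiments observe
*clone sizes*, not clone ages. Standard branching-process analyses condition
on elapsed time, which is usually unknown. `clonedist` instead conditions on
the number of cells: because each division adds exactly one cell, the state
of a clone at a given **size** depends only on the sequence of division
outcomes — the embedded jump chain — and not on their timing. This yields
exact, closed or recursively computable distributions, and makes parameters
estimable from a single snapshot.

Two processes are covered.

**Progenitor/differentiated (P/D) homeostasis.** A proliferating cell divides
into PP, PD or DD with probabilities `a`, `b`, `c` (`a+b+c=1`). The number of
P cells in a clone of size `n` performs a lattice walk (up/flat/down) absorbed
at zero, so

- `P_{n,k}`, the probability of `k` P cells at size `n`, is the weighted
  Motzkin path value `m_{n-1,k-1}`;
- `P_{n,0} = c·m_{n-2,0}` is the probability the clone is fully
  differentiated (frozen) at exactly size `n` — a gambler's-ruin first
  passage with generating function
  `G(t) = (1 − bt − √((1−bt)² − 4act²)) / 2a`;
- the extinction probability is `1` if `a ≤ c`, else `c/a`;
- the fate probabilities are estimable from counts `N₂, N₃, N₄` of small
  fully differentiated clones via `b = N₃/N₂`, `ac = b·(N₄/N₃) − b²`, and the
  roots of `x² − (1−b)x + ac`.

**Growing colony with mutation.** In a Yule colony grown from one non-mutant
cell, each non-mutant division produces a mutant daughter with probability
`μ₁ = 1 − μ₀`; mutants may divide `ρ` times faster. The mutant count at
colony size `k` follows an exact jump-chain recurrence (a size-indexed
Luria–Delbrück distribution, with `p₀ = μ₀^{k-1}`), and the subclone
structure under per-division `Poisson(λ)` mutations (`μ₀ = e^{−λ}`) has exact
laws: the mutation frequency spectrum, the clone count `C − 1 ~ Bin(k−1, μ₁)`,
the clone-size distribution, and the mutations carried by a random clone.

Every exact law is paired with a seedable stochastic simulator (jump-chain
and continuous-time) used as an independent oracle in the test suite.

## Worked example

Estimate division-fate probabilities from counts of small fully
differentiated clones (here: 259, 72 and 53 clones of sizes 2, 3 and 4
observed in a 2086-clone keratinocyte culture):

```python
>>> from clonedist import CloneSizeCounts, estimate_fate_ratio
>>> est = estimate_fate_ratio(CloneSizeCounts({2: 259, 3: 72, 4: 53}),
...                           root_policy="a_greater")
>>> round(est.b_hat, 3), round(est.ac_hat, 3)
(0.278, 0.127)
>>> est.fate
FateProbabilities(a=0.41550422476252163, b=0.27799227799227805, c=0.3065034972452004)
```

So `b ≈ 0.278` of divisions produce one proliferating and one differentiated
daughter, and with the proliferation-skewed root assignment (`a > c`, as
indicated by the continued presence of expanding clones) the remaining mass
splits into `a ≈ 0.416` (two proliferating) and `c ≈ 0.307` (two
differentiated). Such a clone founder eventually stops proliferating with
probability `c/a ≈ 0.740`:

```python
>>> from clonedist import FateProbabilities, extinction_probability
>>> extinction_probability(FateProbabilities(0.415, 0.278, 0.307))
0.7397590361445784
```

The same interfaces are available from a shell, e.g.

```sh
clonedist fate estimate --counts counts.csv          # counts.csv: size,count
clonedist ld dist --k 100 --mu1 0.05 --rho 2         # mutant-count table
clonedist subclone spectrum --k 50                   # frequency spectrum
clonedist fixtures counts --a 0.415 --b 0.278 --c 0.307 --n 100000 --seed 1
```

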