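# Methods

## Model and scope

`clonedist` computes distributions for two cell-division processes, both
conditioned on clone/colony *size* rather than elapsed time.

**Homeostatic P/D process.** A clone grows from one proliferating (P) cell.
Each division is PP, PD or DD with constant probabilities `(a, b, c)` on the
probability simplex; differentiated (D) cells never divide and are never lost
(no apoptosis, no shedding). Conditioning on size removes all rate and
cell-cycle information: the P-cell count is a walk taking one up/flat/down
step per division, absorbed at zero. All quantities follow from weighted
Motzkin path counts:

- `P_{n,k} = m_{n-1,k-1}` for `k ≥ 1`, where `m_{n,k}` is computed two
  independent ways — a closed summation over Dyck-triangle counts
  (ballot numbers `D(n,k) = C(n,(n+k)/2) − C(n,(n+k)/2+1)`, themselves
  verified against the one-step recurrence and exhaustive enumeration), and
  the one-step recurrence `m_{n+1,k} = c·m_{n,k+1} + b·m_{n,k} + a·m_{n,k-1}`.
  The recurrence is the binding definition; the closed form must match it.
- `P_{n,0} = c·m_{n-2,0}` (ruin at exactly size `n`), cross-checked against
  the Taylor coefficients of `G(t) = (1 − bt − √((1−bt)² − 4act²))/(2a)`,
  whose constant and linear numerator terms vanish identically. The radical
  is expanded by the power-series square-root recurrence, exactly in rational
  mode. A renewal identity built from unrestricted-walk return probabilities
  (`u_n = Σ f_r v_{n-r}`, multinomial sums) provides a third, independent
  consistency check.
- Extinction probability: `G(1)` with `1 − b = a + c` collapses the radical
  to `|a − c|`, giving 1 for `a ≤ c` and `c/a` otherwise. The degenerate
  input `b = 1` is rejected (the walk never moves).

The size-1 clone is defined as unit mass at `k = 1` so that the conservation
identity `Σ_{k≥1} P_{n,k} + Σ_{j=2}^n P_{j,0} = 1` holds for every `n ≥ 2`
(verified exactly in rational mode for `n ≤ 30` over interior and boundary
parameter sets).

**Growing colony with mutation.** A Yule colony grows from one non-mutant
cell. At a non-mutant division one daughter is mutant with probability
`μ₁ = 1 − μ₀`; mutants breed true (no back mutation, no mutant-specific
loss). With relative mutant fitness `ρ` (ratio of division rates), competing
exponential clocks make the next divider mutant with probability
`ρm/(ρm + n)` — only the ratio matters, so the size-indexed law is exact for
any rates. The mutant-count distribution at size `k` is iterated by the
one-step recurrence (neutral and selection variants are separate code paths,
with the `ρ = 1` reduction asserted in tests, not assumed). The mean
non-mutant count has the closed product form `Π_{j=1}^{k-1} (j + μ₀)/j`,
validated against the distribution; the variance is accumulated from the
distribution (no closed second moment is exposed).

**Subclone structure.** Refining mutations to unique labels, each division
spawns `Poisson(λ)` new mutations with `μ₀ = e^{−λ}` (so "at least one
mutation" reproduces the per-division mutation probability `μ₁`). Under
neutral growth the carrier count of a marked lineage is a Pólya urn, giving:
the conditional kernels `s^{(j,k)}_r` and frequency spectrum
`𝔭^{(k)}_r = (1/(k−1)) Σ_j s^{(j,k)}_r` (a random mutation is uniform over
the `k−1` divisions — the proof's convention; weighting divisions by their
mutation multiplicity would be an alternative not implemented); the clone
count `C − 1 ~ Bin(k−1, μ₁)`; the clone-size distribution (independent
implementation of the same urn, founded at division `i`, asserted equal to
the spectrum entry-for-entry); and the mutations carried by a random clone,
modeled as `Z + Σ_{r<i} X_r N_r` with `X_r ~ Bernoulli(1/(r+1))`,
`N_r ~ Poisson(λ)` i.i.d., and `Z` the founding division's own count.

`Z` is taken as **zero-truncated** Poisson(λ): a clone exists only because
its founding division produced at least one mutation. This convention is
isolated behind the `mode` switch of `mutations_per_clone` so an alternative
(plain Poisson) could be swapped in; the Monte-Carlo mode and the genotype
simulator use the same convention, which is what makes the cross-check
meaningful.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| `a, b, c` | PP/PD/DD division probabilities | simplex | none (data-driven) |
| `μ₁` | per-division mutant-daughter probability | [0, 1] | none |
| `ρ` | mutant/non-mutant division-rate ratio | > 0 | 1 (neutral) |
| `λ` | mean mutations per division | ≥ 0 | tied to `μ₀ = e^{−λ}` |
| `β_n, β_m` | absolute division rates (continuous-time sims) | > 0 | 1, `ρ·β_n` |

Units: probabilities per division; `β` per cell per unit time (the unit is
arbitrary — no size-indexed quantity depends on it).

## Estimation

The ratio estimator uses only the counts of fully differentiated clones of
sizes 2–4: `b̂ = N₃/N₂`, `âĉ = b̂(N₄/N₃) − b̂²`, then `(a, c)` as roots of
`x² − (1−b̂)x + âĉ`. The data are symmetric in `a` and `c`; `root_policy`
(default `a_greater`) encodes the side information that still-expanding
clones indicate a proliferation skew. Moments are carried as exact rationals;
only the root extraction is floating point.

**Conditioning caveat.** The root split has discriminant `(a − c)²` at the
truth. Near-balanced fates (`a ≈ c`, the homeostatic regime) are therefore
statistically unidentifiable from realistic counts: sampling noise makes the
estimated discriminant negative on a sizable fraction of datasets (flagged as
`feasible=False`, never an exception), and near the boundary the `a`/`c`
errors are amplified by `1/(2√disc)`. For the keratinocyte-like fate
`(0.415, 0.278, 0.307)` at 10⁵ simulated clones this amplification puts the
standard error of `â` near 0.02 with ~10% infeasible datasets. `b̂` is always
well conditioned (se ≈ 0.003 at that scale). Reported point estimates are
full precision; three-decimal presentation is formatting only.

The multinomial MLE over sizes `2..n_max` (truncated ruin distribution,
Nelder–Mead from three starts) is an extension using information the ratio
method ignores; boundary solutions and non-convergence are flagged. The
bootstrap resamples the observed count vector multinomially and reports
percentile intervals, counting and excluding infeasible replicates.

## Synthetic data

`generate_count_fixture` emulates a clonal-culture snapshot: independent
single-P-cell clones simulated to absorption, with clones still proliferating
at `max_size` (default 20) censored and excluded — mirroring the
observational exclusion of visibly expanding clones. It reproduces the real
protocol's sampling noise in the size-class counts, but not: measurement
error in cell counting, clone merging/overlap on the dish, heterogeneity of
`(a, b, c)` across cells, or cell loss. Passing recovery tests therefore
demonstrate correctness of the estimator under the model, not robustness to
those real-data effects.

## Numerical policies

- Path counts are exact integers (`math.comb`); weighted values follow the
  arithmetic of the inputs — `Fraction` in, exact out; float in, float out.
  Symbolic inputs work through the same code paths (only `+ * **`).
- Probability-mass drift in the float recurrences is *checked, not repaired*:
  distributions whose mass deviates from 1 by more than 1e−10 raise.
- The mutations-per-clone PGF is expanded as truncated power series with a
  generous tail length; lost mass beyond 1e−9 raises rather than
  renormalizing silently.
- Simulators consume a single `numpy.random.default_rng(seed)`; identical
  config and seed give bit-identical results. The continuous-time mode draws
  real waiting times (rate `β·k`) so its equivalence to the jump chain is an
  empirical test outcome, not a code-sharing artifact.
- Degenerate inputs: `b = 1` is rejected by `extinction_probability` only;
  `μ₀ ∈ {0, 1}` is rejected by `mutations_per_clone`; elsewhere boundary
  fates (`a = 0`, `c = 0`, `a = c`) are first-class and covered by tests.

## Problem sizes used in the checks

Deterministic identities are verified at `n ≤ 30` (conservation, Appendix-
style renewal residual), `n ≤ 60` (ruin series dual route, spectrum ≡ clone
sizes) and `k ≤ 100–500` (zero-class identity, normalization drift).
Stochastic comparisons use 10⁵ replicates for the homeostasis state
distributions, extinction fraction, mutant-count histograms and clone-count
chi-square, and 10⁴ genotype-tracked colonies for the frequency spectrum and
mutations-per-clone — sizes at which each check has adequate power while the
whole suite stays fast.

## Known limitations

- No apoptosis, shedding or other loss of differentiated cells; accommodating
  loss would require an external loss-rate estimate.
- The homeostasis laws hold for any cell-cycle distribution (only the
  sequence of division outcomes matters), but the selection model's
  division-competition probability `ρm/(ρm + n)` relies on exponential
  (memoryless) cell cycles; gamma-distributed cycles would change it.
- Mutation model: one mutant daughter per mutation event (no division-
  independent mutation, no double-mutant divisions, no back mutation); each
  mutation arises once (infinite-sites); mutants suffer no extra loss.
- Spatially regulated tissues (e.g. intestinal crypts) violate the
  constant-probability assumption and are out of scope.
- Per-bin "within 3 SE" simulator checks across many bins carry a designed-in
  few-percent family-wise false-alarm rate; the chi-square variants are the
  better-calibrated joint tests.
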