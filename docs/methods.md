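# Methods

## Model

`prfsim` simulates the single-locus Wright–Fisher process under the
Poisson Random Field (PRF) assumptions: segregating mutations are
completely independent, new mutational events only strike
non-segregating sites (no multiple hits, no linkage), and the mutation
influx is a Poisson process. A generation of organisms is therefore
represented not by genomes but by an array of mutations and their
derived-allele frequencies `x` in each population — the natural unit of
vectorization. Each discrete, non-overlapping generation applies, in
order,

```
x_t,j  →  migration  →  selection  →  binomial drift  →  x_{t+1,j}
```

and then appends the generation's new mutations.

**Effective chromosome number.** All drift and influx intensities are
governed by `Ne = 2N/(1+F)`, interpolating between the outbred diploid
chromosome count (F = 0) and the haploid count (F = 1). `Ne` is the
binomial trial count and must be an integer: we round to nearest and
floor at 1 for any extant population (the formula itself fixes the
value; the rounding rule is ours).

**Migration (I).** Conservative migration: the post-migration frequency
in population j is the average of all populations' frequencies weighted
by the immigrant proportions `m(k,j,t)`, with the resident proportion
implied as `m(j,j,t) = 1 − Σ_{k≠j} m(k,j,t)`. Columns of the migration
matrix must sum to 1 (checked to 1e−9). Populations with N = 0 are not
extant: they carry frequency 0 and neither send nor receive migrants,
which lets pre-split populations exist as array columns without
touching the dynamics.

**Selection (II).** The expected offspring frequency is the
one-generation viability recursion with dominance h and inbreeding F:

```
x' = [x²s + x(1−x)s(F + h − hF) + x] / [x²s + x(1−x)s(F + 2h − 2hF) + 1]
```

with `s = s(j,t,x)` evaluated at the post-migration frequency, allowing
frequency-dependent selection. At F = 0 this is the textbook diploid
recursion `x' = (x²(1+s) + x(1−x)(1+hs)) / w̄`; at F = 1 the haploid
recursion `x(1+s)/(1+sx)`; both identities are asserted in the tests
against independently coded forms. `s > −1` is required; note that for
h outside [0,1] (over/underdominance) mean fitness can still reach zero
at intermediate frequency (e.g. s = 4, h = −1), in which case the
engine raises a model error rather than producing a negative frequency.

**Drift (III).** `x_{t+1} = k/Ne` with `k ~ Binomial(Ne, x')`, giving
mean `x'` and variance `x'(1−x')/Ne`. The trial count is the
*offspring* generation's `Ne(j, t+1)` — the paper-standard Wright–Fisher
convention when the population size changes between generations; the
same offspring-index convention applies to every parameter function.
0 and 1 are absorbing and are passed through without consuming random
draws (an optimization that also keeps absorption exact in floating
point).

**Mutation influx.** Each generation and extant population receives
`n_j ~ Poisson(Ne(j,t)·μ(j,t)·L)` new mutations at frequency `1/Ne(j,t)`
(0 in other populations), appended after drift so they first experience
selection and drift in the following generation. The site count L
enters only through this mean; site identities are never tracked
(infinite-sites bookkeeping, consistent with the PRF no-multiple-hits
assumption). Each mutation carries a unique origin ID
(generation, population, index) enabling age spectra and per-mutation
trajectory recording.

**Compaction.** Mutations lost (x = 0) or fixed (x = 1) across *all
extant* populations are removed every `compact_interval` generations
and once more before returning; removed fixations are logged per
generation as divergence. A mutation fixed in one population but
segregating in another is retained; its frequency there can only leave
1 via migration. Correctness is schedule-invariant (the filter commutes
with the update law since absorbed rows cannot change except by
migration from other rows' columns — and rows are removed only when
absorbed everywhere); the test suite checks distributional invariance
of segregating-site counts across `compact_interval ∈ {1, 10, 100}`.
The default of 10 is purely a memory/speed trade-off.

## Equilibrium initialization

The expected number of segregating mutations at frequency x at
mutation–selection–drift equilibrium is

```
λ_μ(x) = 2μL / (x(1−x)ψ(x)) · ∫_x^1 ψ(y)dy / ∫_0^1 ψ(y)dy,
ψ(y)   = exp(−Ne s(y) y {(2h + (1−2h)y)(1−F) + 2F})
```

where ψ is the scale density of the corresponding diffusion (its
exponent is `−∫ 2M/V` for drift `M = s x(1−x)[(h+F−hF) + x(1−2h)(1−F)]`
and variance `V = x(1−x)/Ne`). In the genic case (h = ½, F = 0) this
reduces exactly to the Sawyer–Hartl density
`2μL(1−e^{−γ(1−x)})/(x(1−x)(1−e^{−γ}))`, γ = Ne·s, which the tests use
as an independent closed form; the neutral limit is `2μL/x`.

Two conventions needed fixing:

* **Per-class reading.** λ_μ(i/Ne) is taken *directly* as the expected
  count in lattice class i/Ne (the continuous density `2NeμL/x ...`
  times the class width 1/Ne). This makes the neutral expected
  segregating-site count `2μL·Ne·H_{Ne−1}` and is the only reading
  consistent with the per-generation influx mean NeμL.
* **Quadrature.** Composite trapezoid on a uniform grid of
  max(Ne, 65536) intervals, one pass of cached cumulative sums serving
  every x (O(grid) total, deterministic). The grid floor keeps the
  O(h²) quadrature error below ~1e−7 relative, comfortably inside the
  1e−6 neutral-closed-form tolerance.

Initialization draws each class count from a Poisson with mean
λ_μ(i/Ne) by inverse-CDF sampling. It covers a single population or
several with zero initial migration (each equilibrates independently);
with active migration there is no product-form equilibrium and a
burn-in must be used instead.

## Randomness and reproducibility

One integer seed per run. Every stochastic operation draws from a
generator seeded by `SeedSequence(seed, spawn_key=(tag, generation,
population))`, with distinct tags for initialization, drift, mutation
influx and SFS sampling, so runs are bit-reproducible for a fixed seed
and the streams for different generations/populations are independent
regardless of array size. Identical-seed runs with different
compaction intervals are *not* bit-identical (array layout differs, so
vector draws bind differently); only the process law is invariant,
which is what the schedule-invariance test checks.

## Spectra

Population spectra bin mutations by lattice class i/Ne (classes 0 and
Ne excluded). Sample spectra draw `k ~ Binomial(n, x)` per mutation —
sampling with replacement, the PRF convention, accurate for n ≪ Ne —
and count outcomes 0 < k < n; a hypergeometric (without-replacement)
option exists. Normalization divides by the segregating-site count.
Spectra export as TSV and as dadi-style `.fs` text (n+1 entries with
masked corners) for interoperability with diffusion-based tools.

## Validation experiments and problem sizes

* **Split-with-growth scenario** (`prfsim.presets.yri_ceu_split_scenario`):
  N_ref = 10,000 diploids at ancestral equilibrium, instant expansion
  to 2N_ref, split after 100 generations with a 0.05·N_ref bottleneck,
  exponential growth to 5N_ref over 900 generations, symmetric
  migration 5e−5, s = −2e−4 (2N_ref·s = −4), h = 0.5, μ = 1e−9,
  L = 2e9. One full run ends with ≈3.16e6 segregating mutations and a
  1001-chromosome sample of the derived population holds ≈5.6e5
  segregating sites (several minutes on one CPU; the binomial drift
  draws dominate).
* **Rescaling.** Dividing sizes and times by c while multiplying s, μ
  and m by c preserves Ne·s, Ne·m and the influx Ne·μ·L, hence the
  normalized spectra. The shape test runs the split scenario at c = 10;
  the invariance test compares two-epoch runs at c = 5 over 50 seeds by
  a KS test on per-seed mean sampled frequencies. The *raw* segregating
  count is not preserved by rescaling (it scales with the lattice
  harmonic number), which is why the count assertions use the
  full-scale run.
* **Exactness checks** run at deliberately small Ne (50–100) where the
  full transition matrix is available: neutral fixation probability
  1/Ne over 50,000 replicate chains, and a chi-square comparison of the
  10-generation frequency distribution against the matrix power.
  Replicate chains are simulated as rows of one mutation array — under
  the PRF they are exactly independent single-locus processes.

## What the synthetic scenarios do and do not show

All inputs are synthetic scenarios of the model itself; passing tests
demonstrate internal correctness (agreement with exact finite-N chains,
closed-form equilibria, and scaling/schedule invariances), not fidelity
to any real population, which would additionally require linkage,
variable mutation spectra and ascertainment. Known limitations: no
linkage or recombination, one derived allele per site (no back- or
recurrent mutation: a mutation fixed in all populations is permanent
divergence), no equilibrium start under migration, and scenarios where
segregating mutations approach the site count L violate the PRF
premise. Selection enters drift only through the expected frequency;
extremely strong selection with small Ne is better served by the exact
chain in `prfsim.oracle`.
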