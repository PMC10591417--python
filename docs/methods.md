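# Model and methods

`senesim` is a forward-time, spatially explicit, individual-based simulator
built to study whether a heritable rate of aging can be positively selected.
Its population lives on an N x N toroidal lattice; each site is empty or
holds one haploid individual. Two quantitative traits are genetically
encoded by binary loci on a single chromosome:

* **Fecundity.** `L_f` loci are compared against a binary target phenotype
  `phi[t]` of the same length. The number of matches `s` sets the
  multiplicative fecundity `b ** s` (`b > 1`), normalized by `b ** L_f`
  where a bounded quantity is wanted. The target is shared by all
  individuals.
* **Rate of aging.** `L_a` loci contribute additively to the age-dependent
  mortality coefficient `alpha = 0.01 * (number of ON senescence alleles)`.

The per-generation hazard of an individual of age `tau` (in generations) is

    delta = delta0 + alpha * tau     if tau <= tau_max,
    delta = 1                        otherwise,

with `tau_max = floor((1 - delta0) / alpha)` the maximum lifespan and
`delta0` the age-independent baseline (extrinsic) mortality. An individual
with `alpha = 0` keeps the baseline hazard at every age: mutation cannot
push mortality below `delta0`, and a non-ager is "genetically immortal" in
the sense that only extrinsic hazards kill it.

The chromosome interleaves the two locus classes in a uniformly random,
run-fixed order, so a single crossover point can separate any subsets of
fecundity and senescence loci.

## Selective environments

* **Directional selection** is a moving target: `phi` starts all-zero and
  every `T` generations ("fitness period dilution") one randomly chosen
  element opposite to the current phase flips, ascending until the pattern
  saturates and then descending, giving a triangle wave with exact period
  `2 * T * L_f` generations and Hamming distance 1 between consecutive
  states. A flip is applied at the start of generation `t` whenever
  `t % T == 0` (first flip at `t = T`); the phase reverses on the flip that
  reaches saturation, with no double flip at the turning point.
* **Stabilizing selection** keeps a static target of i.i.d. fair-coin
  elements; deviations are selected against and the standing aging rate is
  set by mutation-selection balance and drift.

## Dynamics

A generation is `N * N` elementary Monte Carlo steps at independently,
uniformly drawn sites (with replacement — classic asynchronous updating;
sites skipped in a generation let a few individuals exceed `tau_max`),
followed by one age-updating step that increments every survivor.

One elementary step:

1. **Occupied site** — the occupant dies with probability `delta`. A site
   freed by death is immediately exposed to the repopulation rule below,
   within the same step. This choice is what keeps the grid saturated
   (empty-site fraction below 1e-3 at all tested parameters) while mean
   mortality at the evolved state is ~0.3-0.45; the alternative, leaving
   the site empty until it is drawn again, would hold ~25-30% of sites
   empty at such mortalities and contradicts both the saturation and the
   short-lifespan equilibrium this model family is known for.
2. **Empty site** — parent candidates are the occupied sites of the
   n-Moore neighborhood (the `(2n+1)^2 - 1` sites within Chebyshev distance
   `n`, torus-wrapped). One parent is drawn with probability proportional
   to raw fecundity `b ** s` (normalization cancels in proportional
   selection). Asexual mode: the offspring is a mutated copy. Sexual mode:
   a second, distinct parent is drawn fecundity-proportionally from the
   remaining candidates (dioecy, without replacement); with fewer than two
   candidates the site stays empty. The offspring is the mutated
   single-point recombinant: with probability `p_rec` a crossover point is
   drawn uniformly from the `L - 1` internal inter-locus positions (at
   least one gene from each parent), the parent contributing the left
   segment chosen by a fair coin; otherwise one uniformly chosen parent is
   copied. Mutation afterwards flips each fecundity bit with `p_f` and each
   senescence bit with `p_a`, independently. Newborns start at age 0.
3. **Diffusion** — after every elementary step, `D` swaps in expectation
   (`floor(D)` plus a Bernoulli remainder) of uniformly random
   orthogonally/diagonally adjacent site pairs, chosen independently of the
   focal site; empty sites participate. `D = 0.5` calibrates to one lattice
   step per site per generation (each swap displaces two sites; `N^2`
   trials per generation), i.e. `2 D` moves/site/generation, verified by
   instrumented swap counting.

Initialization fills every site: ages `floor(U(0, 1/delta0))`, senescence
alleles all 0 (a non-aging founding population, so any aging that appears
has evolved), fecundity alleles i.i.d. fair coins.

## Parameters

| symbol | meaning | default |
|---|---|---|
| N | lattice side | 200 |
| L_f, L_a | fecundity / senescence loci | 50, 50 |
| delta0 | baseline mortality per generation | 0.05 |
| b | fecundity base | 1.2 |
| n | Moore neighborhood radius | 1 |
| T | generations per target flip | 10 |
| p_rec | crossover probability | 1 |
| p_f, p_a | per-bit mutation rates | 0.01 |
| D | expected swaps per elementary update | 0 |

Defaults are the standard conditions of the study design this package
implements; desk-scale work reduces `N` and the run length (see below), not
these rates.

## Variants and protocols

* **Configuration-field limit** — the 8 parent candidates are distinct
  sites drawn uniformly from the whole lattice (excluding the focal site,
  without replacement so dioecy stays meaningful). This destroys
  relatedness between the vacated site and its candidates and is the
  mean-field control for kin selection.
* **Monomorphic fertility** — all individuals share the target's own
  fecundity pattern and `p_f` is forced to 0; only senescence alleles
  evolve. Used for the extrinsic-mortality (`delta0`) sweeps.
* **Evolvable baseline** — the hazard becomes the age-independent
  `0.002 + 0.01 * (ON senescence alleles)`; the 0.002 floor excludes
  infinite longevity. Senescence alleles mutate normally. Separates the
  age-dependence of mortality from its evolvability.
* **Fixed alpha** — senescence alleles preset to the requested rate for
  every individual and `p_a = 0` (rejected otherwise), to measure how
  target tracking depends on a clamped aging rate.
* **Sweeps** (`experiments.run_sweep`) — one full run per value x
  replicate; replicate seeds are `base_seed + replicate`, shared across
  values (a paired design). Equilibrium quantities are window means; the
  default window is the trailing 60% of the run, scaled from the full-scale
  convention of discarding the first ~2000 transient generations.
* **Invasions** (`experiments.run_invasion`) — equilibrate the resident,
  replace a random fraction of occupants by invaders, run out a horizon.
  Invaders keep the fecundity genotype of the resident they replace (the
  comparison isolates the aging trait), carry the requested number of ON
  senescence alleles, start at age 0 and bear a neutral lineage tag that is
  maternally inherited (copied from the first-drawn parent). Establishment
  is judged by the final frequency of individuals carrying any senescence
  allele, which is exact when the resident has `p_a = 0`; the maternal tag
  is reported too but is only lineage-exact for asexual populations — under
  recombination it decouples from the senescence alleles within a few
  generations and then drifts, so it cannot measure the fate of the aging
  trait itself. "Relaxation" after an introduction of non-agers means the
  window-mean aging rate returns to within 2 temporal standard deviations
  of the pre-introduction window.

## Numerical and implementation choices

* The generation loop is compiled (numba); the same update logic is also
  exposed as plain-Python reference operators (`elementary_update`,
  `fill_empty_site`, ...) used by the enumeration-style unit tests. The
  compiled path is itself pinned by distributional tests (crossover-point
  uniformity via offspring composition, closed-form single-occupant
  survival `(1 - delta0/9)^9` on a 3x3 grid, swap-count calibration,
  realized-death-rate consistency with the mean hazard).
* One master seed per run is split (`numpy.random.SeedSequence`) into the
  initialization stream and the kernel stream; sequential kernel calls in
  multi-phase protocols continue one stream, so every protocol is a pure
  function of its spec. Fecundity weights use a precomputed power table;
  parent choice is cumulative-sum roulette with the last candidate as the
  numerical-tie fallback.
* Per-site caches of the senescence sum and the target match count are
  maintained incrementally (a target flip toggles exactly one locus's match
  for every individual) and are cross-checked against recomputation in
  tests.
* Summaries average over occupied sites only and are taken at the
  end-of-generation state (after the age update, so newborns are censused
  at age 1). The fecundity-aging correlation uses the population formula
  and reports NaN (never 0) when a variance vanishes, as do all means on an
  empty lattice.
* The aging-rate gradient profile uses the Chebyshev (Moore) metric on the
  torus. Pair enumeration is exhaustive for `N < 65` (ring offsets are
  deduplicated modulo N, which matters at distance `N/2`) and
  random-pair-sampled above; distances above `N/2` are rejected as they do
  not exist on the torus.
* `D > 1` is allowed and means several swaps per elementary update, since
  the diffusion parameter is an expected swap count, not a probability.

## Desk scales and what the tests show

Full-scale conditions (200x200, 10,000 generations, 100-replicate sweeps)
are not rerun in the test suite; the suite uses 100x100/4000 generations
for the headline equilibrium and 48x48-64x64 with 1600-3000 generations
for the comparative protocols, with 2-3 fixed seeds per condition and
window means over the post-transient generations. At these scales every
comparative effect is large against the seed-to-seed spread (orderings are
asserted together with rank tests between extreme groups), but the
absolute level of stochastic quantities — especially anything resting on
rare nucleation events — is less settled than at full scale: small
stabilizing-selection lattices occasionally show multi-hundred-generation
drift excursions of the mean aging rate, which the across-seed control
standard deviations honestly inflate. "Statistically indistinguishable"
claims are therefore checked both against the 2-control-SD bound and as an
explicit equivalence margin (at most 10% of the kin-selected elevation may
remain), since a point-null significance test cannot confirm equality.

The simulator is a model, not data: it assumes discrete generations inside
which updating is asynchronous, one individual per site, haploid genetics
with two unlinked-by-role locus classes, no explicit resources, no
density-dependent fecundity, no pleiotropy or epistasis, and a fecundity
target that moves by single-locus steps. Passing tests show the mechanism
(kin-selected, directional-selection-dependent evolution of a mortality
program) operates in this idealized setting; they say nothing about the
magnitude of such effects in real populations.

## Known limitations

* The location of the sharp no-aging transition in the fitness period
  dilution `T` is structurally sensitive. In this implementation the
  directional aging-rate plateau persists to `T ~ 48` and collapses to the
  stabilizing baseline around `T ~ 64-80` (bistable in between: near the
  transition, otherwise-identical seeds split between the aging and
  non-aging attractors), robust to grid sizes 64-200 and run lengths to
  8000 generations. A variant update scheme in which a freed site is *not*
  immediately exposed to repopulation moves the transition down to
  `T ~ 40-48` but holds ~25% of sites empty, which is incompatible with
  the saturated-grid regime every other observable here calibrates
  against. Transition-location estimates from this package should be read
  with that sensitivity in mind; all other reported quantities
  (occupancies, equilibrium ages and rates, thresholds in the mutation
  rate, monotonicities in `n`, `D`, `T`, invasion verdicts, variant
  behavior) are insensitive to it.
* The neutral lineage tag is maternal and therefore not a trait-fate
  tracker under recombination (see Invasions above).
* At `N` below ~32 the stabilizing baseline becomes excursion-prone and
  comparative runs need more seeds than the defaults used here.
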