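# Methods

This note documents the model, the numerical choices, and the scope of the
synthetic data, in the package's own terms. Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## The forward model

A diploid, dioecious Wright–Fisher population of constant size `N` (even;
exactly `N/2` of each sex) evolves in discrete generations. Each individual
carries two chromosomes with two homologs each, on a continuous genetic map
`[0, R]`: a mutation is a real coordinate plus a selection coefficient, and
two haplotypes share a position only by descent (infinite sites), so
homozygosity is exact position equality — no epsilon matching.

One life cycle:

1. **Parent sampling.** For each offspring slot a mother and a father are
   drawn with probability proportional to fitness within their sex
   (equivalently, fitness standardised by the sex's mean). Parents are
   re-drawn on every attempt.
2. **Recombination.** Each gamete takes Poisson(`R`) crossover points uniform
   on `[0, R]`; the source homolog alternates across the resulting intervals
   starting from a uniformly chosen homolog. The same process applies to both
   chromosomes.
3. **Mutation.** Poisson(`U`) new mutations per chromosome per gamete, at
   uniform positions. On the selected chromosome each receives an effect
   drawn from Gamma(shape `β`, mean `S_mean`) on the population scale and
   rescaled as `s = S / (2·Ne_assumed)`; on the neutral chromosome `s = 0`.
4. **Viability.** Fitness is `w = ∏(1 − s/2)` over heterozygous ×
   `∏(1 − s)` over homozygous selected mutations. Offspring with `w ≤ 0` are
   discarded and the attempt repeated until `N` viable offspring exist;
   female slots are filled first, then male, fixing the 1:1 sex ratio.

**Clamped fitness factors.** The raw product can turn *positive* again when
an even number of factors are negative: two heterozygous mutations with
`s = 3` would give `(−0.5)² = 0.25`, and in practice such genotypes acquire
enormous |w| and sweep the population — an algebraic artifact, not a model
feature. Each factor is therefore clamped at zero: any genotype carrying one
individually lethal factor (het `s ≥ 2`, hom `s ≥ 1`) is inviable. For all
viable genotypes the clamp changes nothing. The production kernel also
rejects offspring immediately when a newly drawn mutation has `s ≥ 2`
(equivalent, since such an offspring is het-lethal regardless of everything
else); this makes the realised influx of surviving mutations
Poisson(`U · P(s < 2)`) with a truncated gamma DFE, exactly as viability
selection dictates.

**Fixed mutations** stay in genotypes (they cost fitness when selected).
Neutral sites fixed in the whole population are purged periodically
(`purge_every`, default 100 generations); they are monomorphic in every
sample and fitness-free, so purging only bounds memory.

**Initialisation** is a mutation-free population; steady state is defined
solely by the burn-in of `10·N` generations (the default).

Two engines implement this identically: a pure-Python reference
(`wright_fisher`, used by the unit tests and for op-level semantics) and a
compiled kernel (`_wf_kernel`, numba) used for production runs. They share
the model but not random streams; both are seeded and bit-reproducible.
When `U = 0` the chromosomes are permanently empty and the kernel reduces to
a vectorised quantitative-locus-only loop.

## The quantitative locus and Ne calibration

A single neutral locus sits at coordinate `R/2` of the selected chromosome
and travels with whichever homolog spans that point after recombination.
Each offspring receives Poisson(`mut_mean = 1`) perturbations, each adding
N(0, `effect_sd² = 1`) to one of its two allelic values chosen uniformly, so
the mutational variance input is `Vm = 1` per individual per generation.

At drift–mutation equilibrium the variance of allelic values across the
`2N` gene copies is `Ne · Vm`: each copy receives `Vm/2` of variance per
generation and variance decays at rate `1/(2Ne)`. (The variance of
*genotypic* values — the sum of the two alleles — equilibrates at twice
this, `2·Ne·Vm`; the package estimates `Ne` from the allelic variance, which
is the quantity whose expectation is `N·Vm` in the neutral case. Both
identities were verified by direct simulation before the estimator was
fixed.) `estimate_ne = variance / Vm`.

Because effects are specified as `S = 2·Ne·s`, an `Ne` must be assumed
*before* a run. `build_standard_curve` maps assumed → realised `Ne` and
`self_consistent_ne()` picks the fixed point (nearest grid point, linearly
interpolated when the sign of the difference flips). For the strongly
deleterious acceptance runs the package uses `Ne_assumed = N = 500` without
a per-run curve: at `S_mean = 10000, β = 0.4` about 59% of new mutations are
het-lethal and die at birth (no background-selection effect beyond random
culling), and most of the remainder are purged within a few generations, so
the self-consistent `Ne` stays near `N`. The curve machinery remains
available for regimes with substantial linked weak selection.

Two kernels use an exact thinning identity for the locus: Poisson(`m`)
mutation events assigned to a uniformly chosen allele are equivalent to two
independent Poisson(`m/2`) streams per allele, and `k` N(0, `sd²`)
increments sum to N(0, `k·sd²`). The event-level operation (`mutate_qlocus`)
is kept literal.

## Site frequency spectra and p_lth

Unfolded SFSs count polymorphic sites by derived-allele count
`i = 1 … n−1` in a sample of `n` haplotypes (default: 10 individuals = 20
haplotypes; assumed length 20 000 sites). The derived state is mutation
presence; sites absent or fixed in the sample are excluded.

The gamma + lethal correction multiplies every *selected* SFS entry by
`1 − p_lth`; the neutral SFS is never scaled. Scaled entries stay
fractional — rounding would inject un-modelled noise — and the likelihood
accepts fractional counts through the continuous `lnΓ(y+1)` extension of the
factorial. Because the correction rescales the data, likelihoods under
different `p_lth` describe different datasets; the profile table carries a
`data_rescaled` flag as a standing reminder that they are not comparable as
a model-selection criterion.

Datasets live in a small text dialect (header `<#neutral> <#selected> <n>`,
one whitespace-separated line per SFS with `n−1` entries plus the length,
neutral first; one block per species). It is self-consistent, not
byte-compatible with any external tool.

## Poisson random field analytics

`H(S, x)` is evaluated as `e^{−Sx}(1 − e^{−S(1−x)}) / (x(1−x)(1 − e^{−S}))`,
which never overflows; below `S = 1e−4` the neutral limit `1/x` (and
`θ/i` for the expected counts) is exact to working precision — diffusion
expressions degrade as `S → 0`, so the switch is explicit.

The frequency integral `θ ∫ B(i; n, x) H(S, x) dx` cancels the `1/x`
endpoint singularity against the `x^i` binomial factor analytically and is
computed by:

- adaptive quadrature (`expected_count`, the reference path, relative
  tolerance `1e−8`) — reliable up to `S ≈ 5000`; beyond that the fixed
  rules below are the *more* accurate path (checked against 50-digit
  arithmetic);
- fixed Gauss rules (`expected_counts`, the production path): 256-node
  Gauss–Legendre on (0, 1) for `S ≤ 60`, and for larger `S` a 96-node
  Gauss–Laguerre rule on the boundary-layer variable `u = S·x`, where
  `e^{−Sx}` confines all mass. Batched over arrays of `S`, the node
  matrices are shared, so a whole quadrature grid costs a few matrix
  products.

The gamma-DFE mixture `∫ E(P=i | S) Gamma(S; β, S_mean) dS` needs care for
shape `β < 1`: the density has an integrable singularity at `S = 0`, and for
large `S_mean` the small-`S` mass produces nearly all expected polymorphism.
The rule therefore splits at `S_cut = min(60, 30·scale)`:
Gauss–Jacobi with weight `v^{β−1}` on `[0, S_cut]` absorbs the singularity,
and Gauss–Legendre on a log axis handles `[S_cut, S_max]` where the density
spans decades. Weights sum to 1 to ~1e−9 across the whole parameter box,
and the resulting expected SFS sits inside the Monte-Carlo error band of a
100 000-draw per-draw mixture oracle (tested). For `β > 30` the gamma is
effectively a point mass and a mean ± 10 sd Gauss–Legendre window is used
instead.

## Inference engine

`GammaDFEModel` implements the Poisson random field likelihood: each
selected SFS entry is Poisson with the gamma-mixture mean; replicate SFSs
are independent observations of the same mean. `θ` is not optimised: the
neutral expectation `θ/i` gives the closed-form MLE
`θ̂ = Σy / Σ 1/i` from the (pooled) neutral spectra, per species, rescaled
by the selected/neutral length ratio (identical lengths → identical `θ`).
In joint multi-species fits the DFE parameters are shared and `θ` is per
species.

Optimisation is Nelder–Mead in `log S_mean` (box `[1e−2, 1e7]`) and `β`
(box `[0.01, 5]`), with one restart when a simplex collapses onto the box
boundary, from `n_starts` initialisations: random starts draw
`S ~ U(1000, 10000)` and `β ~ U(0.2, 0.8)` (the field's standard
initialisation protocol), and when generating truth is supplied half the
starts begin there. Ties between equal-likelihood starts break toward lower
`S_mean`. All starts are retained in the results object; the "mean
likelihood ± CI" reported by the profile tables is the t-interval across
converged starts. A fully scaled-away dataset (`p_lth = 1`) is flagged
degenerate and reported with the analytic log-likelihood `−Σλ` rather than
optimised.

Confidence intervals throughout are `mean ± t_{0.975, n−1} · sd/√n` with the
sample standard deviation. (A printed-formula variant with `σ/n` instead of
`σ/√n` circulates; the standard t-interval is implemented.)

The lethality threshold for `lethal_fraction` is `s* = 1` (homozygous
inviability) and is exposed as a parameter, since "lethal" conventions
differ (e.g. `s ≥ 1` versus `S ≫ 2Ne`).

## Experiment drivers and problem sizes

Drivers are pure orchestration (simulate → SFS → fit → metrics) and are
byte-reproducible under fixed seeds. The package's desk-scale defaults are
10 replicate populations × 4 optimiser starts where the reference design
used 50 × 10; every output table carries the scale stamp.

Two data sources exist. The single-species accuracy designs (and the
acceptance run) use the full Wright–Fisher route. The multi-species designs
(joint likelihood profiles, the homogenisation tables) default to SFSs drawn
as Poisson noise around the engine's own expectation: the phenomena they
probe — `p_lth` shrinking all selected entries toward zero and thereby
pushing different species' spectra together, inflating a joint likelihood —
are properties of the rescaled data and the likelihood, not of the
simulator. The weakly deleterious trio used there is
`(β, S) = (0.15, 5), (0.40, 20), (0.65, 40)` at `θ = 2000`, matching the
simulator's study conditions (`θ = 4·Ne·U` with `Ne = 500, U = 1`).

The neutral-calibration quantity (steady-state variance at the linked
locus) is measured at the final generation of each `10N`-generation
replicate. A single replicate is one genealogy, so its variance has a
coefficient of variation near 1; the acceptance run uses 600 replicates
(criterion floor: 20) to bring the relative standard error of the mean to
~4%. Time-averaging the last generations was evaluated and rejected: the
autocorrelation time of the variance is of order `N` generations, so a 2N
window only buys a ~1.4× reduction while complicating the protocol.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions exactly: constant `N`,
discrete generations, 1:1 sexes, two unlinked chromosomes with uniform maps,
additive-within/multiplicative-between fitness, gamma effects on the
`2·Ne·s` scale, Poisson mutation and recombination, `10N` burn-in,
20-haplotype samples. It does **not** model demographic change, selfing or
hermaphroditism, dominance other than `h = 1/2`, beneficial mutations,
INDELs, ancestral-state error, or SFS distortion (no nuisance `r_i`
parameters) — all outside scope. Passing tests therefore show the inference
engine's behaviour under the model's own assumptions plus linked selection
and finite-population effects, not robustness to demographic or
ascertainment misspecification in real data.

## Known limitations

- The PRF expectation assumes free recombination between selected sites and
  a single effective size; the simulator's linked, interfering sites make
  the realised `θ` (and weak-mutation behaviour) deviate from the
  independent-sites ideal. This is intrinsic to the design — the mismatch
  between explicit forward simulation and PRF inference is part of what is
  being measured.
- The optimiser is derivative-free; with very flat profiles (high `p_lth`,
  small datasets) different starts can end at different local optima. All
  starts are reported.
- `expected_count`'s adaptive reference degrades above `S ≈ 5000` for large
  `i` (entries ~1e−16 and below); the production rules are validated there
  by arbitrary-precision checks instead.
- Likelihood values under different `p_lth` are not comparable (data
  rescaling); the package annotates but cannot prevent such comparisons.
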