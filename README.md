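# gammalethal

Simulation and inference tools for studying the **"gamma + lethal"** model of
the distribution of fitness effects (DFE) — specifically, how the correction
parameter `p_lth` (the proportion of new mutations assumed too deleterious to
ever appear in a sample of haplotypes) behaves when a gamma-distributed DFE is
fitted to site frequency spectra (SFS) from one or several populations.

## Who this is for

Population geneticists working on DFE inference from polymorphism data.
Strongly deleterious mutations are nearly invisible in samples: at
mutation–selection balance a deleterious allele segregates at frequencies
~1/s, so once `S = 2·Ne·s` exceeds ~100 a mutation has essentially no chance
of being sampled. Several inference tools therefore augment the gamma DFE with
a point mass of "effectively lethal" mutations, implemented by multiplying
every entry of the selected SFS by `1 − p_lth`. This package provides the
machinery to study when that correction helps, when it misleads, and why.

## The model

**Forward simulation.** An individual-based diploid Wright–Fisher population
(`N = 500` by default) with discrete generations and two chromosomes per
individual — one selected, one neutral — on a continuous map `[0, R]`
(infinite sites, `R = 10` crossovers per meiosis on average). Fitness is
multiplicative across loci and additive within (`h = 1/2`):

    w = ∏ (1 − s/2)  ×  ∏ (1 − s)
        heterozygous     homozygous

Selection coefficients of new mutations are drawn from a gamma distribution
with mean `S = 2·Ne·s` and shape `β`, rescaled by an assumed `Ne`. Mutations
arrive at `U = 1` per chromosome per gamete per generation. Offspring with
`w ≤ 0` are inviable and redrawn. A neutral quantitative locus at the centre
of the selected chromosome (mutational variance `Vm = 1` per individual per
generation) measures the realised `Ne` as its steady-state allelic variance
divided by `Vm`.

**Poisson random field analytics.** The expected number of sites where a
derived allele with scaled coefficient `S` appears in `i` of `n` sampled
haplotypes is

    E(P = i) = θ ∫₀¹ B(i; n, x) · H(S, x) dx ,
    H(S, x) = (1 − e^{S(1−x)}) / (x (1−x) (1 − e^S)) ,

with `θ = 4·Ne·μ·L` and positive `S` denoting a deleterious mutation. The
probability that no copy is sampled is `exp(−Σᵢ E(P = i))`.

**Inference.** Counts in each selected SFS entry are independent Poisson with
means given by the gamma mixture of `E(P = i)`; `θ` is profiled out in closed
form from the paired neutral SFS (`θ̂ = Σᵢ yᵢ / Σᵢ 1/i`). `p_lth` rescales
the data before fitting — which also means likelihoods at different `p_lth`
describe *different datasets* and cannot be compared as a model-selection
criterion. Accuracy is scored as `log₂(estimate / truth)`, and the true
proportion of lethals of a gamma DFE is the tail mass
`P(s ≥ 1) = Q(β, 2·Ne·β/S_mean)`.

## Worked example

```python
import numpy as np
from gammalethal import (GammaDFE, GammaDFEModel, PRFParams, prob_absent,
                         lethal_fraction)
from gammalethal.experiments import prf_sfs_dataset

# How invisible are deleterious mutations in a sample of n = 20?
for S in (10, 100, 1000, 5000):
    print(f"S = {S:>5}: P(absent | n=20, theta=1) = "
          f"{prob_absent(PRFParams(theta=1.0, n=20), S):.3f}")

# Fit a gamma DFE to 50 neutral/selected SFS pairs generated from the
# model itself (S_mean = 20, beta = 0.4, theta = 100) with Poisson noise
ds = prf_sfs_dataset([GammaDFE(s_mean=20.0, beta=0.4)], theta=100.0,
                     n=20, replicates=50, seed=42)
res = GammaDFEModel(ds, p_lth=0.0).fit(
    n_starts=4, truth={"s_mean": 20.0, "beta": 0.4}, seed=1)
print(res.summary())
```

prints

```
S =    10: P(absent | n=20, theta=1) = 0.305
S =   100: P(absent | n=20, theta=1) = 0.831
S =  1000: P(absent | n=20, theta=1) = 0.980
S =  5000: P(absent | n=20, theta=1) = 0.996
Gamma DFE fit (Poisson random field likelihood)
================================================
species:            species_1
SFS pairs:          50  (n = 20)
p_lth:              0.000
free parameters:    s_mean, beta
converged:          True
------------------------------------------------
s_mean (mean 2Ne s): 22.235
beta   (gamma shape): 0.371853
theta[species_1]: 99.8213
log-likelihood:     -2059.04
loglik over starts: -2059.04 +/- 6.15e-12 (95% t-CI)
```

The absence probabilities quantify the core problem: even at moderate `θ`, a
mutation with `S = 1000` is missing from 98% of samples. The fit recovers the
generating parameters (`Ŝ = 22.2` vs 20, `β̂ = 0.37` vs 0.4) within the
Poisson noise of a 50-pair dataset, and `lethal_fraction(10000, 0.4, 500)`
= 0.693 — i.e. at `S_mean = 10000` over two-thirds of new mutations are
homozygous-lethal, far above the `p_lth ≤ 0.2` that maximises inference
accuracy (see the experiment drivers).

A command-line interface mirrors the library:
`gammalethal simulate | calibrate-ne | sfs build/scale | prf-curve | infer |
experiment` (see `gammalethal --help`).

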