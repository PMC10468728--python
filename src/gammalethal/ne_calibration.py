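"""Effective population size from a linked neutral quantitative locus.

A single neutral locus sits at the centre of the selected chromosome
(coordinate R/2) and is perturbed in every offspring at a Poisson rate
``mut_mean`` (default 1) by N(0, effect_sd^2) increments to one of its
two allelic values, so the mutational variance input is
``Vm = mut_mean * effect_sd^2`` per individual per generation.  At
drift-mutation equilibrium the variance of the allelic values across
the 2N gene copies equals ``Ne * Vm``: each copy receives variance
``Vm / 2`` per generation and variance decays by ``1/(2 Ne)``, so the
steady state is ``2 Ne * Vm / 2``.  (The variance of *genotypic* values,
the sum of the two alleles, equilibrates at twice this, ``2 Ne * Vm``.)
Estimating the steady-state allelic variance and dividing by ``Vm``
therefore measures the realised Ne, including any reduction caused by
selection on the linked chromosome.

Because selection strengths are specified on the population scale
``S = 2 Ne s``, converting them to ``s`` requires an Ne *before* the
simulation is run.  The standard curve maps each assumed Ne (used for
the rescaling) to the realised steady-state Ne it produces; the
approximately self-consistent point (assumed = realised) is the value
to use for SFS-generating runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import ci
from .wright_fisher import Individual, SimConfig, run_simulation

__all__ = [
    "QLocusParams",
    "StandardCurve",
    "mutate_qlocus",
    "steady_state_variance",
    "estimate_ne",
    "build_standard_curve",
]


@dataclass(frozen=True)
class QLocusParams:
    """Mutation model of the neutral quantitative locus."""

    mut_mean: float = 1.0
    effect_sd: float = 1.0

    @property
    def vm(self) -> float:
        """New mutational variance per individual per generation."""
        return self.mut_mean * self.effect_sd**2

    def __post_init__(self):
        if self.mut_mean < 0 or self.effect_sd <= 0:
            raise ValueError("mut_mean must be >= 0 and effect_sd > 0")


def mutate_qlocus(ind: Individual, params: QLocusParams,
                  rng: np.random.Generator) -> Individual:
    """Apply Poisson(mut_mean) N(0, sd^2) perturbations to random alleles."""
    q = ind.qlocus.copy()
    for _ in range(rng.poisson(params.mut_mean)):
        q[int(rng.integers(2))] += rng.normal(0.0, params.effect_sd)
    ind.qlocus = q
    return ind


def allelic_variance(population) -> float:
    """Variance of the quantitative-locus allelic values over 2N copies."""
    q = np.array([ind.qlocus for ind in population])
    return float(q.ravel().var())


def _batched_neutral_variance(cfg: SimConfig, replicates: int,
                              seed=None) -> list[float]:
    """All replicates of the U = 0 model at once.

    With no genomic mutations the chromosomes are inert and every
    individual has fitness 1, so the life cycle reduces to array
    indexing; a leading replicate axis then makes hundreds of burn-ins
    as cheap as one.  Same model as the per-replicate engine, different
    random streams.
    """
    N, half = cfg.N, cfg.N // 2
    rng = np.random.default_rng(seed)
    q = np.zeros((replicates, N, 2))
    rep = np.arange(replicates)[:, None]
    for _ in range(cfg.burnin):
        mothers = rng.integers(0, half, (replicates, N))
        fathers = rng.integers(half, N, (replicates, N))
        q = np.stack([
            q[rep, mothers, rng.integers(0, 2, (replicates, N))],
            q[rep, fathers, rng.integers(0, 2, (replicates, N))],
        ], axis=2)
        # Poisson(m) events assigned uniformly to one of two alleles are
        # exactly two independent Poisson(m/2) streams, and k increments
        # of N(0, sd^2) sum to N(0, k sd^2)
        k = rng.poisson(cfg.qlocus_mut_mean / 2.0, (replicates, N, 2))
        q = q + (rng.normal(size=(replicates, N, 2))
                 * np.sqrt(k) * cfg.qlocus_effect_sd)
    return [float(v) for v in q.reshape(replicates, -1).var(axis=1)]


def steady_state_variance(cfg: SimConfig, replicates: int,
                          seed=None) -> tuple[float, float, list[float]]:
    """Mean steady-state allelic variance over replicate burn-ins.

    Each replicate runs the model for 10 N generations (by default) and
    records the variance at the final generation.  Returns
    ``(mean, ci_halfwidth, per_replicate_values)``.  When the genomic
    mutation rate is zero the replicates are run in a single batched
    pass; otherwise each runs through the full simulator.
    """
    if replicates < 2:
        raise ValueError("need at least two replicates for a CI")
    if cfg.U == 0.0:
        values = _batched_neutral_variance(cfg, replicates, seed=seed)
    else:
        seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31 - 1)
        values = []
        for s in seeds:
            res = run_simulation(replace(cfg, seed=int(s), qlocus_enabled=True))
            values.append(allelic_variance(res.population))
    mean, hw = ci(values)
    return mean, hw, values


def estimate_ne(variance: float, vm: float) -> float:
    """Realised Ne = steady-state allelic variance / Vm."""
    if variance <= 0 or vm <= 0:
        raise ValueError("variance and Vm must be positive")
    return variance / vm


@dataclass
class StandardCurve:
    """Assumed-vs-realised Ne pairs with replicate CIs."""

    table: pd.DataFrame      # ne_assumed, variance_mean, variance_ci, ne_realized
    replicates: int

    def self_consistent_ne(self) -> float:
        """Ne where assumed and realised sizes agree.

        Picks the grid point minimising |assumed - realised|, refined by
        linear interpolation between adjacent grid points when the
        difference changes sign.
        """
        t = self.table.sort_values("ne_assumed").reset_index(drop=True)
        diff = t["ne_realized"] - t["ne_assumed"]
        sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if sign_change.size:
            j = sign_change[0]
            x0, x1 = t["ne_assumed"].iloc[j], t["ne_assumed"].iloc[j + 1]
            d0, d1 = diff.iloc[j], diff.iloc[j + 1]
            return float(x0 - d0 * (x1 - x0) / (d1 - d0))
        return float(t["ne_assumed"].iloc[diff.abs().idxmin()])


def build_standard_curve(cfg_template: SimConfig, ne_assumed_grid,
                         replicates: int, seed=None) -> StandardCurve:
    """Measure realised Ne for each assumed Ne used for the S -> s rescaling."""
    grid = sorted(float(g) for g in ne_assumed_grid)
    if not grid:
        raise ValueError("ne_assumed_grid must be non-empty")
    rng = np.random.SeedSequence(seed)
    rows = []
    for ne_assumed, child in zip(grid, rng.spawn(len(grid))):
        cfg = replace(cfg_template, ne_assumed=ne_assumed)
        mean, hw, _ = steady_state_variance(
            cfg, replicates, seed=child.generate_state(1)[0] % (2**31 - 1))
        vm = cfg.qlocus_mut_mean * cfg.qlocus_effect_sd**2
        rows.append({
            "ne_assumed": ne_assumed,
            "variance_mean": mean,
            "variance_ci": hw,
            "ne_realized": estimate_ne(mean, vm),
        })
    return StandardCurve(pd.DataFrame(rows), replicates)
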