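"""Individual-based diploid Wright-Fisher simulator with infinite sites.

The model: a population of ``N`` diploids (constant 1:1 sex ratio) with
discrete generations.  Each individual carries two chromosomes, each
with two homologs, on a continuous map ``[0, R]`` -- every real
coordinate is a unique site, so recurrent mutation never happens.  The
first chromosome holds selected mutations whose homozygous effects
``s`` are drawn from a gamma distribution specified on the population
scale ``S = 2*Ne*s`` (mean ``s_mean``, shape ``beta``) and rescaled
with an assumed effective size fixed before the run; the second is
fully neutral.  Fitness is multiplicative across loci and additive
within (h = 1/2):

    w = prod_het (1 - s/2) * prod_hom (1 - s)

Parents are sampled with probability proportional to fitness within
their sex; gametes undergo Poisson(``R``) crossovers at uniform
breakpoints and receive Poisson(``U``) new mutations, independently per
chromosome.  Offspring with ``w <= 0`` are inviable and redrawn (with
fresh parents) until ``N`` viable offspring exist.  A neutral
quantitative locus linked to the centre of the selected chromosome
(used for effective-size calibration, see
:mod:`gammalethal.ne_calibration`) is transmitted with whichever
homolog spans coordinate ``R/2`` after recombination.

Two execution engines share this model: a readable pure-Python
reference used by the unit tests (the functions below), and a compiled
kernel (:mod:`gammalethal._wf_kernel`) used for production runs, which
:func:`run_simulation` selects by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Mutation",
    "Haplotype",
    "Individual",
    "SimConfig",
    "SimulationResult",
    "SimulationError",
    "sample_selection_coefficient",
    "fitness",
    "make_gamete",
    "mutate_gamete",
    "next_generation",
    "run_simulation",
    "sample_haplotypes",
]


class SimulationError(RuntimeError):
    """A generation could not be completed (e.g. a sex with zero fitness)."""


class Mutation(NamedTuple):
    position: float
    s: float


@dataclass(frozen=True)
class Haplotype:
    """A sorted, duplicate-free set of mutations on one homolog."""

    positions: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "s", s)
        if pos.shape != s.shape:
            raise ValueError("positions and s must be parallel arrays")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing (infinite sites)")

    @classmethod
    def empty(cls) -> "Haplotype":
        return cls(np.empty(0), np.empty(0))

    @classmethod
    def from_mutations(cls, mutations: Sequence[Mutation]) -> "Haplotype":
        mutations = sorted(mutations)
        return cls(
            np.asarray([m.position for m in mutations], dtype=float),
            np.asarray([m.s for m in mutations], dtype=float),
        )

    @property
    def mutations(self) -> list[Mutation]:
        return [Mutation(p, s) for p, s in zip(self.positions, self.s)]

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class Individual:
    selected: tuple[Haplotype, Haplotype]
    neutral: tuple[Haplotype, Haplotype]
    sex: str
    qlocus: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        self.qlocus = np.asarray(self.qlocus, dtype=float)
        if self.qlocus.shape != (2,) or not np.all(np.isfinite(self.qlocus)):
            raise ValueError("qlocus must hold two finite allelic values")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (defaults are the standard study conditions)."""

    N: int = 500
    U: float = 1.0
    R: float = 10.0
    s_mean: float = 0.0      # gamma mean on the S = 2*Ne*s scale
    beta: float = 0.4
    ne_assumed: float = 500.0
    burnin_generations: int | None = None   # defaults to 10 N
    seed: int | None = None
    qlocus_enabled: bool = True
    qlocus_mut_mean: float = 1.0
    qlocus_effect_sd: float = 1.0
    record_every: int = 500
    purge_every: int = 100

    def __post_init__(self):
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be even and >= 2 (1:1 sex ratio)")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.s_mean < 0:
            raise ValueError("s_mean must be non-negative")
        if self.ne_assumed <= 0:
            raise ValueError("ne_assumed must be positive")

    @property
    def burnin(self) -> int:
        return 10 * self.N if self.burnin_generations is None else self.burnin_generations


@dataclass
class SimulationResult:
    population: list[Individual]
    log: pd.DataFrame
    cfg: SimConfig


# --------------------------------------------------------------------- operations

def sample_selection_coefficient(cfg: SimConfig, rng: np.random.Generator,
                                 size=None):
    """Draw s: Gamma(shape beta, mean s_mean) on the S scale, then / (2 Ne)."""
    if cfg.beta <= 0:
        raise ValueError("beta must be positive")
    if cfg.s_mean == 0.0:
        return 0.0 if size is None else np.zeros(size)
    scale = cfg.s_mean / cfg.beta / (2.0 * cfg.ne_assumed)
    return rng.gamma(cfg.beta, scale, size=size)


def fitness(ind: Individual) -> float:
    """Multiplicative fitness over the selected chromosome (h = 1/2).

    A mutation present on both homologs (exact position match: mutations
    are shared only by descent) is homozygous with effect ``1 - s``;
    otherwise heterozygous with ``1 - s/2``.  The neutral chromosome and
    the quantitative locus never contribute.

    Individual factors are clamped at zero: a genotype carrying any
    single lethal factor (heterozygous s >= 2, homozygous s >= 1) has
    ``w = 0`` and is inviable.  Without the clamp an even number of
    negative factors would multiply to a large *positive* fitness,
    letting carriers of several lethal mutations take over the
    population -- an artifact of the raw product, not a feature of the
    model.
    """
    h1, h2 = ind.selected
    common, i1, i2 = np.intersect1d(h1.positions, h2.positions,
                                    return_indices=True)
    hom = 1.0 - h1.s[i1]
    het = 1.0 - 0.5 * np.concatenate([np.delete(h1.s, i1), np.delete(h2.s, i2)])
    if np.any(hom <= 0.0) or np.any(het <= 0.0):
        return 0.0
    return float(np.prod(hom) * np.prod(het))


def make_gamete(homolog_pair: tuple[Haplotype, Haplotype], R: float,
                rng: np.random.Generator, return_center_origin: bool = False):
    """Recombine two homologs into one gamete haplotype.

    Poisson(``R``) crossover points fall uniformly on [0, R]; the source
    homolog alternates across crossover intervals, starting from a
    uniformly chosen homolog.  With ``return_center_origin`` the index
    of the homolog contributing coordinate R/2 (carrying the linked
    quantitative locus) is also returned.
    """
    k = rng.poisson(R)
    breaks = np.sort(rng.uniform(0.0, R, size=k))
    start = int(rng.integers(2))
    bounds = np.concatenate([[0.0], breaks, [R]])
    pieces_p, pieces_s = [], []
    for j in range(k + 1):
        src = homolog_pair[(start + j) % 2]
        lo = np.searchsorted(src.positions, bounds[j])
        hi = np.searchsorted(src.positions, bounds[j + 1])
        pieces_p.append(src.positions[lo:hi])
        pieces_s.append(src.s[lo:hi])
    gamete = Haplotype(np.concatenate(pieces_p), np.concatenate(pieces_s))
    if return_center_origin:
        origin = (start + int(np.searchsorted(breaks, R / 2.0))) % 2
        return gamete, origin
    return gamete


def mutate_gamete(g: Haplotype, cfg: SimConfig, selected: bool,
                  rng: np.random.Generator) -> Haplotype:
    """Add Poisson(U) new mutations at uniform positions.

    Selected-chromosome mutations get gamma-distributed effects; neutral
    ones have s = 0.
    """
    m = rng.poisson(cfg.U)
    if m == 0:
        return g
    new_p = rng.uniform(0.0, cfg.R, size=m)
    new_s = (np.asarray(sample_selection_coefficient(cfg, rng, size=m))
             if selected else np.zeros(m))
    order = np.argsort(new_p)
    new_p, new_s = new_p[order], new_s[order]
    idx = np.searchsorted(g.positions, new_p)
    return Haplotype(np.insert(g.positions, idx, new_p),
                     np.insert(g.s, idx, new_s))


def _mutate_qlocus_inplace(q: np.ndarray, cfg: SimConfig,
                           rng: np.random.Generator) -> None:
    for _ in range(rng.poisson(cfg.qlocus_mut_mean)):
        q[int(rng.integers(2))] += rng.normal(0.0, cfg.qlocus_effect_sd)


def next_generation(pop: list[Individual], cfg: SimConfig,
                    rng: np.random.Generator,
                    generation: int | None = None) -> list[Individual]:
    """One life cycle: fitness-weighted mating until N viable offspring.

    Female slots are filled first, then male slots, guaranteeing an
    exact 1:1 sex ratio.  Parents are re-sampled on every attempt;
    inviable offspring (w <= 0) are discarded and redrawn.
    """
    half = cfg.N // 2
    females = [i for i in pop if i.sex == "female"]
    males = [i for i in pop if i.sex == "male"]
    wf = np.array([fitness(i) for i in females])
    wm = np.array([fitness(i) for i in males])
    if wf.sum() <= 0 or wm.sum() <= 0:
        raise SimulationError(
            f"total fitness of a sex is zero at generation {generation}")
    pf, pm = wf / wf.sum(), wm / wm.sum()
    offspring: list[Individual] = []
    for slot in range(cfg.N):
        sex = "female" if slot < half else "male"
        while True:
            mother = females[rng.choice(len(females), p=pf)]
            father = males[rng.choice(len(males), p=pm)]
            gm, om = make_gamete(mother.selected, cfg.R, rng,
                                 return_center_origin=True)
            gf, of = make_gamete(father.selected, cfg.R, rng,
                                 return_center_origin=True)
            gm = mutate_gamete(gm, cfg, True, rng)
            gf = mutate_gamete(gf, cfg, True, rng)
            child = Individual(selected=(gm, gf),
                               neutral=(Haplotype.empty(), Haplotype.empty()),
                               sex=sex)
            if fitness(child) <= 0:
                continue
            nm = mutate_gamete(make_gamete(mother.neutral, cfg.R, rng),
                               cfg, False, rng)
            nf = mutate_gamete(make_gamete(father.neutral, cfg.R, rng),
                               cfg, False, rng)
            child.neutral = (nm, nf)
            if cfg.qlocus_enabled:
                child.qlocus = np.array([mother.qlocus[om], father.qlocus[of]])
                _mutate_qlocus_inplace(child.qlocus, cfg, rng)
            offspring.append(child)
            break
    return offspring


def _segregating(haps: list[np.ndarray], n_haps: int) -> int:
    nonempty = [h for h in haps if h.size]
    if not nonempty:
        return 0
    _, counts = np.unique(np.concatenate(nonempty), return_counts=True)
    return int(np.sum(counts < n_haps))


def _purge_fixed_neutral(pop: list[Individual]) -> None:
    """Drop neutral sites fixed in the whole population (fitness-neutral)."""
    haps = [h.positions for i in pop for h in i.neutral]
    if not all(h.size for h in haps):
        return
    pooled, counts = np.unique(np.concatenate(haps), return_counts=True)
    fixed = pooled[counts == len(haps)]
    if not fixed.size:
        return
    for ind in pop:
        ind.neutral = tuple(
            Haplotype(h.positions[~np.isin(h.positions, fixed)],
                      h.s[~np.isin(h.positions, fixed)])
            for h in ind.neutral
        )


def _reference_run(cfg: SimConfig) -> SimulationResult:
    rng = np.random.default_rng(cfg.seed)
    half = cfg.N // 2
    pop = [
        Individual(selected=(Haplotype.empty(), Haplotype.empty()),
                   neutral=(Haplotype.empty(), Haplotype.empty()),
                   sex="female" if i < half else "male")
        for i in range(cfg.N)
    ]
    records = []
    for gen in range(cfg.burnin):
        pop = next_generation(pop, cfg, rng, generation=gen)
        if cfg.purge_every and (gen + 1) % cfg.purge_every == 0:
            _purge_fixed_neutral(pop)
        if (gen + 1) % cfg.record_every == 0 or gen + 1 == cfg.burnin:
            records.append(_log_row(pop, gen + 1))
    if not records:
        records.append(_log_row(pop, cfg.burnin))
    return SimulationResult(pop, pd.DataFrame(records), cfg)


def _log_row(pop: list[Individual], generation: int) -> dict:
    q = np.array([i.qlocus for i in pop])
    return {
        "generation": generation,
        "mean_fitness": float(np.mean([fitness(i) for i in pop])),
        "seg_neutral": _segregating(
            [h.positions for i in pop for h in i.neutral], 2 * len(pop)),
        "seg_selected": _segregating(
            [h.positions for i in pop for h in i.selected], 2 * len(pop)),
        "qlocus_var": float(q.ravel().var()),
    }


def run_simulation(cfg: SimConfig, engine: str = "fast") -> SimulationResult:
    """Burn in a population from a mutation-free start.

    Runs ``cfg.burnin`` (default 10 N) generations and returns the final
    population plus a log of mean fitness, segregating-site counts and
    quantitative-locus variance at each recorded interval.  Fully
    reproducible from ``cfg.seed``.

    ``engine="fast"`` uses the compiled kernel; ``engine="reference"``
    the pure-Python implementation above (identical model, different
    random streams).
    """
    if engine == "reference":
        return _reference_run(cfg)
    if engine != "fast":
        raise ValueError("engine must be 'fast' or 'reference'")
    from ._wf_kernel import run_kernel

    return run_kernel(cfg)


def sample_haplotypes(pop: Sequence[Individual], n_individuals: int,
                      rng: np.random.Generator):
    """Sample individuals without replacement; return their haplotypes.

    Returns ``(neutral, selected)`` lists of ``2 * n_individuals``
    haplotypes each, the raw material for one SFS pair.
    """
    if n_individuals > len(pop):
        raise ValueError("cannot sample more individuals than the population holds")
    idx = rng.choice(len(pop), size=n_individuals, replace=False)
    neutral = [h for i in idx for h in pop[i].neutral]
    selected = [h for i in idx for h in pop[i].selected]
    return neutral, selected
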