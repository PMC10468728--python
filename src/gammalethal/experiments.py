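"""Scripted experiment drivers: simulation -> SFS -> inference -> metrics.

Each driver reproduces one of the study designs at a configurable
(default: desk) scale and returns a tidy DataFrame; given an output
directory it also writes TSVs and convenience plots.  Drivers are pure
orchestration over the simulator, the SFS tools and the inference
engine -- rerunning with identical seeds reproduces every table.

Two data sources exist for inference experiments.  ``wf`` runs the
individual-based Wright-Fisher simulator (the expensive, fully explicit
route used for the single-species accuracy experiments).  ``prf`` draws
replicate SFSs as Poisson noise around the PRF expectation of the same
gamma DFE -- the model the likelihood assumes -- and is used for the
multi-species likelihood-artifact experiments, where the mechanism
under study (p_lth pushing different spectra together) does not depend
on how the spectra were generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .inference import FitSpec, GammaDFEModel
from .metrics import ci, inaccuracy, lethal_fraction
from .prf import GammaDFE, PRFParams, expected_sfs_gamma, prob_absent
from .sfs import SFS, SFSDataset, build_unfolded_sfs, scale_sfs, sfs_dispersion
from .wright_fisher import SimConfig, run_simulation, sample_haplotypes

__all__ = [
    "ExperimentPlan",
    "WEAK_TRIO",
    "simulate_sfs_dataset",
    "prf_sfs_dataset",
    "single_species_accuracy",
    "multispecies_likelihood_profile",
    "run_experiment",
]

#: the weakly deleterious three-species set (beta, S pairs)
WEAK_TRIO = (GammaDFE(5.0, 0.15), GammaDFE(20.0, 0.40), GammaDFE(40.0, 0.65))

#: scaled mutation rate matching the simulator's study conditions
#: (theta = 4 * Ne * U with Ne = 500 and U = 1 per chromosome)
DEFAULT_THETA = 2000.0


@dataclass
class ExperimentPlan:
    """Reduced-scale experiment layout.

    The reference design uses 50 replicate simulations and 10 optimiser
    starts per fit; the desk-scale default is 10 x 4, recorded in the
    ``scale_factor`` stamp carried into every output table.
    """

    s_grid: tuple = tuple(range(1000, 10001, 1000))
    beta_grid: tuple = (0.4,)
    plth_grid: tuple = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
    replicates: int = 10
    n_starts: int = 4
    n_individuals: int = 10
    seed: int | None = None
    sim: SimConfig = field(default_factory=SimConfig)

    @property
    def scale_factor(self) -> str:
        return f"{self.replicates}x{self.n_starts} (reference 50x10)"


# ------------------------------------------------------------------ data sources

def simulate_sfs_dataset(s_mean: float, beta: float, replicates: int,
                         cfg: SimConfig | None = None, n_individuals: int = 10,
                         length: float = 20000.0, seed=None,
                         species: str = "species_1") -> SFSDataset:
    """Replicate Wright-Fisher runs -> one neutral/selected SFS pair each."""
    cfg = cfg or SimConfig()
    cfg = replace(cfg, s_mean=s_mean, beta=beta)
    seeds = np.random.SeedSequence(seed).generate_state(2 * replicates) % (2**31 - 1)
    pairs = []
    for r in range(replicates):
        res = run_simulation(replace(cfg, seed=int(seeds[2 * r])))
        rng = np.random.default_rng(int(seeds[2 * r + 1]))
        neutral, selected = sample_haplotypes(res.population, n_individuals, rng)
        n = 2 * n_individuals
        pairs.append((
            build_unfolded_sfs(neutral, n, length, kind="neutral"),
            build_unfolded_sfs(selected, n, length, kind="selected"),
        ))
    return SFSDataset(pairs, [species] * replicates)


def prf_sfs_dataset(dfes, theta: float = DEFAULT_THETA, n: int = 20,
                    replicates: int = 20, length: float = 20000.0,
                    seed=None, species=None) -> SFSDataset:
    """Poisson draws around the PRF expectation, one block per species."""
    rng = np.random.default_rng(seed)
    params = PRFParams(theta=theta, n=n)
    if species is None:
        species = [f"species_{k + 1}" for k in range(len(dfes))]
    neutral_exp = theta / np.arange(1, n)
    pairs, labels = [], []
    for dfe, label in zip(dfes, species):
        lam = expected_sfs_gamma(params, dfe)
        for _ in range(replicates):
            pairs.append((
                SFS(rng.poisson(neutral_exp).astype(float), n, length, "neutral"),
                SFS(rng.poisson(lam).astype(float), n, length, "selected"),
            ))
            labels.append(label)
    return SFSDataset(pairs, labels)


# ------------------------------------------------------------------ fig 1 / fig 4

def absence_probability_table(thetas=(0.1, 1.0, 10.0), ns=(10, 100, 1000),
                              s_min: float = 10.0, s_max: float = 5000.0,
                              points: int = 40) -> pd.DataFrame:
    """P(no copy sampled) on a log-spaced S grid for each (n, theta)."""
    S_grid = np.geomspace(s_min, s_max, points)
    rows = [
        {"S": S, "n": n, "theta": theta,
         "prob_absent": prob_absent(PRFParams(theta=theta, n=n), S)}
        for theta in thetas for n in ns for S in S_grid
    ]
    return pd.DataFrame(rows)


def lethal_fraction_table(s_grid=tuple(range(1000, 10001, 1000)),
                          beta: float = 0.4, ne: float = 500.0,
                          s_star: float = 1.0) -> pd.DataFrame:
    """True proportion of lethals for each simulated S (lower bound on
    the proportion of strongly deleterious mutations)."""
    return pd.DataFrame({
        "S": list(s_grid),
        "beta": beta,
        "lethal_fraction": [lethal_fraction(S, beta, ne, s_star) for S in s_grid],
    })


# ------------------------------------------------------------------ single species

def _fit_rows(dataset: SFSDataset, p_lth: float, spec: FitSpec, seed,
              truth: dict) -> list[dict]:
    model = GammaDFEModel(dataset, p_lth=p_lth, free=spec.free, fixed=spec.fixed)
    res = model.fit(n_starts=spec.n_starts, truth=spec.truth, seed=seed)
    rows = []
    for _, start in res.starts.iterrows():
        row = {
            "p_lth": p_lth,
            "s_hat": float(start["s_mean"]),
            "beta_hat": float(start["beta"]),
            "loglik": float(start["loglik"]),
            "converged": bool(start["converged"]),
            "init_mode": start["init_mode"],
        }
        if truth:
            row["inaccuracy_s"] = inaccuracy(row["s_hat"], truth["s_mean"])
            row["inaccuracy_beta"] = inaccuracy(row["beta_hat"], truth["beta"])
        rows.append(row)
    return rows


def single_species_accuracy(s_true: float, beta_true: float,
                            plan: ExperimentPlan,
                            dataset: SFSDataset | None = None) -> pd.DataFrame:
    """Accuracy of (S, beta) inference across the p_lth grid for one DFE.

    Simulates ``plan.replicates`` populations (unless a pre-built
    dataset is supplied), pools the SFS pairs into one dataset, and fits
    the free-(S, beta) model at each p_lth with ``plan.n_starts``
    optimiser starts (half initialised at the truth).  One row per
    (p_lth, start) with the estimates and their log2 inaccuracies.
    """
    ss = np.random.SeedSequence(plan.seed)
    data_seed, *fit_seeds = (s.generate_state(1)[0] % (2**31 - 1)
                             for s in ss.spawn(1 + len(plan.plth_grid)))
    if dataset is None:
        dataset = simulate_sfs_dataset(
            s_true, beta_true, plan.replicates, cfg=plan.sim,
            n_individuals=plan.n_individuals, seed=data_seed)
    truth = {"s_mean": s_true, "beta": beta_true}
    rows = []
    for p, fseed in zip(plan.plth_grid, fit_seeds):
        spec = FitSpec(free=("s_mean", "beta"), p_lth=float(p),
                       n_starts=plan.n_starts, truth=truth)
        rows.extend(_fit_rows(dataset, float(p), spec, fseed, truth))
    out = pd.DataFrame(rows)
    out.insert(0, "beta_true", beta_true)
    out.insert(0, "s_true", s_true)
    out["scale_factor"] = plan.scale_factor
    return out


def best_plth(cell: pd.DataFrame) -> float:
    """p_lth minimising the mean |log2(S_hat / S_true)| over starts."""
    score = cell.groupby("p_lth")["inaccuracy_s"].apply(lambda v: v.abs().mean())
    return float(score.idxmin())


def accuracy_grid(plan: ExperimentPlan) -> pd.DataFrame:
    """Single-species accuracy over the plan's full (S, beta) grid."""
    frames = []
    ss = np.random.SeedSequence(plan.seed)
    for s_true in plan.s_grid:
        for beta_true in plan.beta_grid:
            sub = replace_plan_seed(plan, ss)
            frames.append(single_species_accuracy(s_true, beta_true, sub))
    return pd.concat(frames, ignore_index=True)


def replace_plan_seed(plan: ExperimentPlan, ss: np.random.SeedSequence):
    child = ss.spawn(1)[0]
    out = ExperimentPlan(**{**plan.__dict__})
    out.seed = int(child.generate_state(1)[0] % (2**31 - 1))
    return out


# ------------------------------------------------------------------ multi species

def multispecies_likelihood_profile(
        dfes=WEAK_TRIO, plth_grid=(0.0, 0.3, 0.6, 0.9),
        replicates: int = 20, n_starts: int = 4, theta: float = DEFAULT_THETA,
        n: int = 20, seed=None, fixed_s: float | None = None,
        fixed_beta: float | None = None,
        dataset: SFSDataset | None = None) -> pd.DataFrame:
    """Joint shared-parameter fit of several species across a p_lth grid.

    By default beta is inferred jointly and S is fixed at a randomly
    sampled value from the standard U(1000, 10000) initialisation range
    (pass ``fixed_s`` to pin it, or ``fixed_beta`` to instead fix beta
    and infer S).  Reports the mean and 95% t-CI of the per-start
    likelihoods at each p_lth; note these are likelihoods of
    *differently rescaled data* and are not a model-selection criterion.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    if dataset is None:
        dataset = prf_sfs_dataset(dfes, theta=theta, n=n,
                                  replicates=replicates,
                                  seed=ss.spawn(1)[0])
    if fixed_beta is not None:
        free, fixed = ("s_mean",), {"beta": float(fixed_beta)}
    else:
        if fixed_s is None:
            fixed_s = float(rng.uniform(1000.0, 10000.0))
        free, fixed = ("beta",), {"s_mean": float(fixed_s)}
    rows = []
    for p in plth_grid:
        model = GammaDFEModel(dataset, p_lth=float(p), free=free, fixed=fixed)
        res = model.fit(n_starts=n_starts,
                        seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)))
        lls = res.starts.loc[res.starts["converged"], "loglik"]
        mean_ll, hw = ci(lls.to_numpy()) if len(lls) > 1 else (float(lls.iloc[0]), 0.0)
        rows.append({
            "p_lth": float(p), "loglik_mean": mean_ll, "loglik_ci": hw,
            "loglik_best": res.llf, "s_mean": res.s_mean, "beta": res.beta,
            **{f"fixed_{k}": v for k, v in fixed.items()},
        })
    return pd.DataFrame(rows)


def sfs_homogenization(dfes=WEAK_TRIO, plth_grid=(0.0, 0.3, 0.6, 0.9),
                       replicates: int = 20, theta: float = DEFAULT_THETA,
                       n: int = 20, seed=None) -> pd.DataFrame:
    """Per-entry selected-SFS means and across-species dispersion by p_lth."""
    ss = np.random.SeedSequence(seed)
    per_species = [
        prf_sfs_dataset([dfe], theta=theta, n=n, replicates=replicates,
                        seed=child, species=[f"species_{k + 1}"])
        for k, (dfe, child) in enumerate(zip(dfes, ss.spawn(len(dfes))))
    ]
    rows = []
    for p in plth_grid:
        scaled = [
            SFSDataset(
                [(neu, scale_sfs(sel, float(p))) for neu, sel in ds.pairs],
                list(ds.species))
            for ds in per_species
        ]
        disp = sfs_dispersion(scaled)
        for k, ds in enumerate(scaled):
            mean_counts = np.mean([pair[1].counts for pair in ds.pairs], axis=0)
            half = [ci([pair[1].counts[j] for pair in ds.pairs])[1]
                    for j in range(n - 1)]
            for j in range(n - 1):
                rows.append({
                    "p_lth": float(p), "species": ds.species[0],
                    "entry": j + 1, "mean_count": mean_counts[j],
                    "ci": half[j],
                    "across_species_sd": float(disp["sd"].iloc[j]),
                })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ dispatch

def run_experiment(which: str, plan: ExperimentPlan | None = None,
                   out_dir=None) -> pd.DataFrame:
    """Run a named figure-style experiment design at the plan's scale."""
    plan = plan or ExperimentPlan()
    if which == "fig1":
        table = absence_probability_table()
    elif which == "fig2":
        table = accuracy_grid(plan)
    elif which == "fig3":
        table = accuracy_grid(replace_plan(plan, s_grid=(50, 250, 2500),
                                           beta_grid=(0.15, 0.40, 0.65)))
    elif which == "fig4":
        table = lethal_fraction_table(s_grid=plan.s_grid)
    elif which == "fig5":
        table = multispecies_likelihood_profile(
            plth_grid=plan.plth_grid, replicates=plan.replicates,
            n_starts=plan.n_starts, seed=plan.seed)
    elif which == "fig6":
        table = sfs_homogenization(replicates=plan.replicates, seed=plan.seed)
    elif which == "fig7":
        frames = [
            multispecies_likelihood_profile(
                plth_grid=plan.plth_grid, replicates=plan.replicates,
                n_starts=plan.n_starts, seed=plan.seed, fixed_beta=b)
            for b in (plan.beta_grid if len(plan.beta_grid) > 1
                      else (0.15, 0.40, 0.65))
        ]
        table = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown experiment {which!r}")
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"{which}.tsv", sep="\t", index=False)
        _plot(which, table, out_dir / f"{which}.png")
    return table


def replace_plan(plan: ExperimentPlan, **kw) -> ExperimentPlan:
    out = ExperimentPlan(**{**plan.__dict__})
    for k, v in kw.items():
        setattr(out, k, v)
    return out


def _plot(which: str, table: pd.DataFrame, path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if which == "fig1":
        for (n, theta), sub in table.groupby(["n", "theta"]):
            ax.semilogx(sub["S"], sub["prob_absent"],
                        label=f"n={n}, theta={theta}")
        ax.set_xlabel("S = 2 Ne s")
        ax.set_ylabel("P(absent from sample)")
        ax.legend(fontsize=6)
    elif which in ("fig2", "fig3"):
        agg = (table.groupby(["s_true", "p_lth"])["inaccuracy_s"]
               .mean().reset_index())
        for s_true, sub in agg.groupby("s_true"):
            ax.plot(sub["p_lth"], sub["inaccuracy_s"], "o-", label=f"S={s_true}")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("p_lth")
        ax.set_ylabel("mean log2(S_hat / S_true)")
        ax.legend(fontsize=6)
    elif which == "fig4":
        ax.plot(table["S"], table["lethal_fraction"], "o-")
        ax.set_xlabel("S")
        ax.set_ylabel("true lethal fraction")
    elif which in ("fig5", "fig7"):
        for key, sub in table.groupby(table.get("fixed_beta", "fixed_s_mean"),
                                      dropna=False):
            ax.errorbar(sub["p_lth"], sub["loglik_mean"], yerr=sub["loglik_ci"],
                        fmt="o-", label=str(key))
        ax.set_xlabel("p_lth")
        ax.set_ylabel("mean log-likelihood")
        ax.legend(fontsize=6)
    elif which == "fig6":
        for (p, sp), sub in table.groupby(["p_lth", "species"]):
            ax.plot(sub["entry"], sub["mean_count"], "o-", ms=2,
                    label=f"p={p} {sp}")
        ax.set_xlabel("SFS entry")
        ax.set_ylabel("mean count")
        ax.legend(fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
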