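"""Compiled Wright-Fisher generation loop (numba).

Same life cycle as :mod:`gammalethal.wright_fisher`, restructured as a
single jitted burn-in over flat arrays: haplotypes are sorted float64
position arrays (selected ones carry a parallel s array), individuals
``i`` own homologs ``2*i`` and ``2*i + 1``, females are indices
``0 .. N/2 - 1``.  Viability is checked before the neutral chromosome
and quantitative locus are built, since only selected mutations enter
fitness.  Fixed neutral sites are purged periodically; they are
monomorphic in every sample and fitness-neutral, so this only bounds
memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import List

from .wright_fisher import (Haplotype, Individual, SimConfig,
                            SimulationError, SimulationResult)

_EMPTY = np.empty(0, dtype=np.float64)


@njit(cache=True)
def _gamete(p1, s1, p2, s2, R):
    """Crossover two homologs; also report which contributes R/2."""
    k = np.random.poisson(R)
    start = 0 if np.random.random() < 0.5 else 1
    if p1.shape[0] == 0 and p2.shape[0] == 0:
        # gamete is empty either way; only the R/2 origin needs the breaks
        left = 0
        for _ in range(k):
            if np.random.uniform(0.0, R) < R * 0.5:
                left += 1
        return np.empty(0), np.empty(0), (start + left) % 2
    breaks = np.sort(np.random.uniform(0.0, R, k))
    idx1 = np.searchsorted(p1, breaks)
    idx2 = np.searchsorted(p2, breaks)
    total = 0
    a1 = 0
    a2 = 0
    cur = start
    for j in range(k + 1):
        e1 = idx1[j] if j < k else p1.shape[0]
        e2 = idx2[j] if j < k else p2.shape[0]
        total += (e1 - a1) if cur == 0 else (e2 - a2)
        a1, a2, cur = e1, e2, 1 - cur
    out_p = np.empty(total)
    out_s = np.empty(total)
    pos = 0
    a1 = 0
    a2 = 0
    cur = start
    for j in range(k + 1):
        e1 = idx1[j] if j < k else p1.shape[0]
        e2 = idx2[j] if j < k else p2.shape[0]
        if cur == 0:
            for t in range(a1, e1):
                out_p[pos] = p1[t]
                out_s[pos] = s1[t]
                pos += 1
        else:
            for t in range(a2, e2):
                out_p[pos] = p2[t]
                out_s[pos] = s2[t]
                pos += 1
        a1, a2, cur = e1, e2, 1 - cur
    origin = (start + np.searchsorted(breaks, R * 0.5)) % 2
    return out_p, out_s, origin


@njit(cache=True)
def _gamete_pos(p1, p2, R):
    """Positions-only crossover (neutral chromosome)."""
    k = np.random.poisson(R)
    start = 0 if np.random.random() < 0.5 else 1
    if p1.shape[0] == 0 and p2.shape[0] == 0:
        return np.empty(0)
    breaks = np.sort(np.random.uniform(0.0, R, k))
    idx1 = np.searchsorted(p1, breaks)
    idx2 = np.searchsorted(p2, breaks)
    total = 0
    a1 = 0
    a2 = 0
    cur = start
    for j in range(k + 1):
        e1 = idx1[j] if j < k else p1.shape[0]
        e2 = idx2[j] if j < k else p2.shape[0]
        total += (e1 - a1) if cur == 0 else (e2 - a2)
        a1, a2, cur = e1, e2, 1 - cur
    out_p = np.empty(total)
    pos = 0
    a1 = 0
    a2 = 0
    cur = start
    for j in range(k + 1):
        e1 = idx1[j] if j < k else p1.shape[0]
        e2 = idx2[j] if j < k else p2.shape[0]
        if cur == 0:
            for t in range(a1, e1):
                out_p[pos] = p1[t]
                pos += 1
        else:
            for t in range(a2, e2):
                out_p[pos] = p2[t]
                pos += 1
        a1, a2, cur = e1, e2, 1 - cur
    return out_p


@njit(cache=True)
def _merge_pos(p, new_p):
    n, m = p.shape[0], new_p.shape[0]
    out = np.empty(n + m)
    i = 0
    j = 0
    k = 0
    while i < n and j < m:
        if p[i] <= new_p[j]:
            out[k] = p[i]
            i += 1
        else:
            out[k] = new_p[j]
            j += 1
        k += 1
    while i < n:
        out[k] = p[i]
        i += 1
        k += 1
    while j < m:
        out[k] = new_p[j]
        j += 1
        k += 1
    return out


@njit(cache=True)
def _merge(p, s, new_p, new_s):
    n, m = p.shape[0], new_p.shape[0]
    out_p = np.empty(n + m)
    out_s = np.empty(n + m)
    i = 0
    j = 0
    k = 0
    while i < n and j < m:
        if p[i] <= new_p[j]:
            out_p[k] = p[i]
            out_s[k] = s[i]
            i += 1
        else:
            out_p[k] = new_p[j]
            out_s[k] = new_s[j]
            j += 1
        k += 1
    while i < n:
        out_p[k] = p[i]
        out_s[k] = s[i]
        i += 1
        k += 1
    while j < m:
        out_p[k] = new_p[j]
        out_s[k] = new_s[j]
        j += 1
        k += 1
    return out_p, out_s


@njit(cache=True)
def _fitness(p1, s1, p2, s2):
    # merge-walk: equal positions are homozygous (shared by descent).
    # Factors are clamped at zero: any lethal factor means w = 0.
    w = 1.0
    i = 0
    j = 0
    n1, n2 = p1.shape[0], p2.shape[0]
    while i < n1 and j < n2:
        if p1[i] == p2[j]:
            fac = 1.0 - s1[i]
            i += 1
            j += 1
        elif p1[i] < p2[j]:
            fac = 1.0 - 0.5 * s1[i]
            i += 1
        else:
            fac = 1.0 - 0.5 * s2[j]
            j += 1
        if fac <= 0.0:
            return 0.0
        w *= fac
    while i < n1:
        fac = 1.0 - 0.5 * s1[i]
        if fac <= 0.0:
            return 0.0
        w *= fac
        i += 1
    while j < n2:
        fac = 1.0 - 0.5 * s2[j]
        if fac <= 0.0:
            return 0.0
        w *= fac
        j += 1
    return w


@njit(cache=True)
def _count_segregating(haps, n_haps):
    total = 0
    for h in haps:
        total += h.shape[0]
    if total == 0:
        return 0
    pooled = np.empty(total)
    k = 0
    for h in haps:
        for t in range(h.shape[0]):
            pooled[k] = h[t]
            k += 1
    pooled = np.sort(pooled)
    seg = 0
    run_start = 0
    for t in range(1, total + 1):
        if t == total or pooled[t] != pooled[run_start]:
            if t - run_start < n_haps:
                seg += 1
            run_start = t
    return seg


@njit(cache=True)
def _purge_fixed(haps):
    n_haps = len(haps)
    cand = haps[0]
    if cand.shape[0] == 0:
        return
    fixed = np.empty(cand.shape[0])
    n_fixed = 0
    for t in range(cand.shape[0]):
        pos = cand[t]
        everywhere = True
        for h_idx in range(1, n_haps):
            h = haps[h_idx]
            j = np.searchsorted(h, pos)
            if j >= h.shape[0] or h[j] != pos:
                everywhere = False
                break
        if everywhere:
            fixed[n_fixed] = pos
            n_fixed += 1
    if n_fixed == 0:
        return
    fixed = fixed[:n_fixed]
    for h_idx in range(n_haps):
        h = haps[h_idx]
        out = np.empty(h.shape[0] - n_fixed)
        k = 0
        j = 0
        for t in range(h.shape[0]):
            if j < n_fixed and h[t] == fixed[j]:
                j += 1
            else:
                out[k] = h[t]
                k += 1
        haps[h_idx] = out[:k]


@njit(cache=True)
def _burnin(sel_p, sel_s, neu_p, q, w, N, U, R, beta, s_scale, burnin,
            qlocus_on, q_mut_mean, q_sd, record_every, purge_every,
            rec_gen, rec_fit, rec_qvar, rec_segn, rec_segs):
    half = N // 2
    n_rec = 0
    status = 0
    for gen in range(burnin):
        cum_f = np.cumsum(w[:half])
        cum_m = np.cumsum(w[half:])
        if cum_f[half - 1] <= 0.0 or cum_m[half - 1] <= 0.0:
            status = -(gen + 1)  # a sex with zero total fitness
            break
        new_sel_p = List()
        new_sel_s = List()
        new_neu_p = List()
        new_q = np.zeros((N, 2))
        new_w = np.empty(N)
        for slot in range(N):
            gm_p = np.empty(0)
            gm_s = np.empty(0)
            gf_p = np.empty(0)
            gf_s = np.empty(0)
            om = 0
            of = 0
            m = 0
            f = half
            wc = 0.0
            attempts = 0
            while True:
                attempts += 1
                if attempts > 1_000_000:
                    status = -(gen + 1)
                    break
                m = np.searchsorted(cum_f, np.random.random() * cum_f[half - 1],
                                    side="right")
                f = half + np.searchsorted(cum_m,
                                           np.random.random() * cum_m[half - 1],
                                           side="right")
                if m >= half:
                    m = half - 1
                if f >= N:
                    f = N - 1
                # draw the offspring's new mutations first: a new
                # heterozygous-lethal effect (s >= 2) is inviable no
                # matter what the parents contribute, so the gametes
                # need not be built at all
                km = np.random.poisson(U)
                kf = np.random.poisson(U)
                if s_scale > 0.0:
                    sm_new = np.random.gamma(beta, s_scale, km)
                    sf_new = np.random.gamma(beta, s_scale, kf)
                    lethal = False
                    for t in range(km):
                        if sm_new[t] >= 2.0:
                            lethal = True
                            break
                    if not lethal:
                        for t in range(kf):
                            if sf_new[t] >= 2.0:
                                lethal = True
                                break
                    if lethal:
                        continue
                else:
                    sm_new = np.zeros(km)
                    sf_new = np.zeros(kf)
                gm_p, gm_s, om = _gamete(sel_p[2 * m], sel_s[2 * m],
                                         sel_p[2 * m + 1], sel_s[2 * m + 1], R)
                gf_p, gf_s, of = _gamete(sel_p[2 * f], sel_s[2 * f],
                                         sel_p[2 * f + 1], sel_s[2 * f + 1], R)
                if km > 0:
                    pm_new = np.random.uniform(0.0, R, km)
                    order = np.argsort(pm_new)
                    gm_p, gm_s = _merge(gm_p, gm_s, pm_new[order], sm_new[order])
                if kf > 0:
                    pf_new = np.random.uniform(0.0, R, kf)
                    order = np.argsort(pf_new)
                    gf_p, gf_s = _merge(gf_p, gf_s, pf_new[order], sf_new[order])
                wc = _fitness(gm_p, gm_s, gf_p, gf_s)
                if wc > 0.0:
                    break
            if status < 0:
                break
            # viable: build the neutral chromosome and quantitative locus
            nm_p = _gamete_pos(neu_p[2 * m], neu_p[2 * m + 1], R)
            nf_p = _gamete_pos(neu_p[2 * f], neu_p[2 * f + 1], R)
            km = np.random.poisson(U)
            if km > 0:
                nm_p = _merge_pos(nm_p, np.sort(np.random.uniform(0.0, R, km)))
            kf = np.random.poisson(U)
            if kf > 0:
                nf_p = _merge_pos(nf_p, np.sort(np.random.uniform(0.0, R, kf)))
            if qlocus_on:
                new_q[slot, 0] = q[m, om]
                new_q[slot, 1] = q[f, of]
                for _ in range(np.random.poisson(q_mut_mean)):
                    a = 0 if np.random.random() < 0.5 else 1
                    new_q[slot, a] += np.random.normal() * q_sd
            new_sel_p.append(gm_p)
            new_sel_p.append(gf_p)
            new_sel_s.append(gm_s)
            new_sel_s.append(gf_s)
            new_neu_p.append(nm_p)
            new_neu_p.append(nf_p)
            new_w[slot] = wc
        if status < 0:
            break
        sel_p, sel_s, neu_p, q, w = new_sel_p, new_sel_s, new_neu_p, new_q, new_w
        if purge_every > 0 and (gen + 1) % purge_every == 0:
            _purge_fixed(neu_p)
        if (gen + 1) % record_every == 0 or gen + 1 == burnin:
            rec_gen[n_rec] = gen + 1
            rec_fit[n_rec] = w.mean()
            rec_qvar[n_rec] = q.ravel().var()
            rec_segn[n_rec] = _count_segregating(neu_p, 2 * N)
            rec_segs[n_rec] = _count_segregating(sel_p, 2 * N)
            n_rec += 1
    return status, n_rec, sel_p, sel_s, neu_p, q, w


def _seed_population(N: int):
    sel_p = List()
    sel_s = List()
    neu_p = List()
    for _ in range(2 * N):
        sel_p.append(_EMPTY.copy())
        sel_s.append(_EMPTY.copy())
        neu_p.append(_EMPTY.copy())
    return sel_p, sel_s, neu_p


def _run_qlocus_only(cfg: SimConfig) -> SimulationResult:
    """Vectorised path for U = 0: chromosomes stay mutation-free forever,
    so only the quantitative locus has dynamics and the whole generation
    reduces to array operations (every individual has w = 1)."""
    import pandas as pd

    N, half = cfg.N, cfg.N // 2
    rng = np.random.default_rng(cfg.seed)
    q = np.zeros((N, 2))
    records = []
    for gen in range(cfg.burnin):
        mothers = rng.integers(0, half, N)
        fathers = rng.integers(half, N, N)
        # the crossover start homolog is uniform, so the homolog carrying
        # the central locus is uniform as well
        q = np.column_stack([
            q[mothers, rng.integers(0, 2, N)],
            q[fathers, rng.integers(0, 2, N)],
        ])
        if cfg.qlocus_enabled:
            # thinned form: Poisson(m) hits on a uniform allele are two
            # independent Poisson(m/2) streams; k N(0, sd^2) increments
            # sum to N(0, k sd^2)
            k = rng.poisson(cfg.qlocus_mut_mean / 2.0, (N, 2))
            q = q + rng.normal(size=(N, 2)) * np.sqrt(k) * cfg.qlocus_effect_sd
        if (gen + 1) % cfg.record_every == 0 or gen + 1 == cfg.burnin:
            records.append({
                "generation": gen + 1, "mean_fitness": 1.0,
                "seg_neutral": 0, "seg_selected": 0,
                "qlocus_var": float(q.ravel().var()),
            })
    pop = [
        Individual(selected=(Haplotype.empty(), Haplotype.empty()),
                   neutral=(Haplotype.empty(), Haplotype.empty()),
                   sex="female" if i < half else "male",
                   qlocus=q[i].copy())
        for i in range(N)
    ]
    return SimulationResult(pop, pd.DataFrame(records), cfg)


def run_kernel(cfg: SimConfig) -> SimulationResult:
    """Run the burn-in through the compiled kernel; wrap as Individuals."""
    import pandas as pd

    if cfg.U == 0.0:
        return _run_qlocus_only(cfg)
    N = cfg.N
    sel_p, sel_s, neu_p = _seed_population(N)
    q = np.zeros((N, 2))
    w = np.ones(N)
    burnin = cfg.burnin
    n_rec_max = burnin // cfg.record_every + 2
    rec_gen = np.zeros(n_rec_max, dtype=np.int64)
    rec_fit = np.zeros(n_rec_max)
    rec_qvar = np.zeros(n_rec_max)
    rec_segn = np.zeros(n_rec_max, dtype=np.int64)
    rec_segs = np.zeros(n_rec_max, dtype=np.int64)
    seed = cfg.seed if cfg.seed is not None else np.random.SeedSequence().entropy
    seed = int(seed) % (2**32 - 1)
    s_scale = (cfg.s_mean / cfg.beta / (2.0 * cfg.ne_assumed)
               if cfg.s_mean > 0 else 0.0)
    status, n_rec, sel_p, sel_s, neu_p, q, w = _run(
        sel_p, sel_s, neu_p, q, w, N, cfg.U, cfg.R, cfg.beta, s_scale,
        burnin, cfg.qlocus_enabled, cfg.qlocus_mut_mean, cfg.qlocus_effect_sd,
        cfg.record_every, max(cfg.purge_every, 0), seed,
        rec_gen, rec_fit, rec_qvar, rec_segn, rec_segs)
    if status < 0:
        raise SimulationError(
            f"total fitness of a sex is zero at generation {-status - 1}")
    half = N // 2
    pop = [
        Individual(
            selected=(Haplotype(sel_p[2 * i], sel_s[2 * i]),
                      Haplotype(sel_p[2 * i + 1], sel_s[2 * i + 1])),
            neutral=(Haplotype(neu_p[2 * i], np.zeros(neu_p[2 * i].shape[0])),
                     Haplotype(neu_p[2 * i + 1],
                               np.zeros(neu_p[2 * i + 1].shape[0]))),
            sex="female" if i < half else "male",
            qlocus=q[i].copy(),
        )
        for i in range(N)
    ]
    log = pd.DataFrame({
        "generation": rec_gen[:n_rec],
        "mean_fitness": rec_fit[:n_rec],
        "seg_neutral": rec_segn[:n_rec],
        "seg_selected": rec_segs[:n_rec],
        "qlocus_var": rec_qvar[:n_rec],
    })
    return SimulationResult(pop, log, cfg)


@njit(cache=True)
def _run(sel_p, sel_s, neu_p, q, w, N, U, R, beta, s_scale, burnin,
         qlocus_on, q_mut_mean, q_sd, record_every, purge_every, seed,
         rec_gen, rec_fit, rec_qvar, rec_segn, rec_segs):
    np.random.seed(seed)
    return _burnin(sel_p, sel_s, neu_p, q, w, N, U, R, beta, s_scale,
                   burnin, qlocus_on, q_mut_mean, q_sd, record_every,
                   purge_every, rec_gen, rec_fit, rec_qvar,
                   rec_segn, rec_segs)
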