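"""Compiled (numba) simulation kernels and model packing.

The engines in :mod:`stochan.mc_engine` and :mod:`stochan.da_engine`
flatten a :class:`~stochan.models.MembraneModel` into plain arrays
(:func:`pack_model`) and hand them to the jitted kernels below.  Rate
functions are evaluated exactly inside the kernels through a small
family encoding (see :mod:`stochan.rates`); schemes using
:class:`~stochan.rates.CustomRate` must fall back to the python
backend.

Layout conventions
------------------
States of all populations are concatenated (``pop_soff`` offsets), as
are transition pairs (``pop_eoff``).  Directed rate ``d`` is the
forward rate of pair ``d`` for ``d < E`` and the backward rate of pair
``d - E`` otherwise.  The last state of each population is the
redundant one: the DA kernel integrates the other ``S_p - 1``
fractions and closes the population with ``1 - sum`` each step, so the
total fraction is conserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["PackedModel", "pack_model", "da_kernel", "mc_kernel"]


# ---------------------------------------------------------------------------
# packing


@dataclass
class PackedModel:
    pop_soff: np.ndarray  # (P+1,) state offsets
    pop_eoff: np.ndarray  # (P+1,) edge offsets
    esrc: np.ndarray  # (E,) global source state (lower index of pair)
    edst: np.ndarray  # (E,) global target state
    fams: np.ndarray  # (2E,) rate family codes
    pars: np.ndarray  # (2E, 3)
    scales: np.ndarray  # (2E,)
    N: np.ndarray  # (P,) channels per population
    cond_g: np.ndarray  # (C,)
    cond_E: np.ndarray  # (C,)
    cond_foff: np.ndarray  # (C+1,)
    cond_fstate: np.ndarray  # (F,) global state index
    cond_fpow: np.ndarray  # (F,)
    term_N: np.ndarray  # (C,) channel count backing each current term
    open_idx: np.ndarray  # (P,) global open-state index per population
    current_names: list

    @property
    def n_states(self) -> int:
        return int(self.pop_soff[-1])

    @property
    def n_pairs(self) -> int:
        return int(self.pop_eoff[-1])


def pack_model(model) -> PackedModel:
    """Flatten a membrane model into kernel arrays.

    The packed form is cached on the model object; models are treated
    as immutable once they have been simulated.
    """
    cached = getattr(model, "_packed", None)
    if cached is not None:
        return cached
    pops = model.populations
    pop_soff = np.zeros(len(pops) + 1, dtype=np.int64)
    pop_eoff = np.zeros(len(pops) + 1, dtype=np.int64)
    for p, pop in enumerate(pops):
        pop_soff[p + 1] = pop_soff[p] + pop.scheme.n_states
        pop_eoff[p + 1] = pop_eoff[p] + pop.scheme.n_pairs
    E = int(pop_eoff[-1])
    esrc = np.zeros(E, dtype=np.int64)
    edst = np.zeros(E, dtype=np.int64)
    fams = np.zeros(2 * E, dtype=np.int64)
    pars = np.zeros((2 * E, 3))
    scales = np.zeros(2 * E)
    for p, pop in enumerate(pops):
        for k, pair in enumerate(pop.scheme.pairs):
            e = int(pop_eoff[p]) + k
            esrc[e] = pop_soff[p] + pair.i
            edst[e] = pop_soff[p] + pair.j
            for d, rate in ((e, pair.forward), (E + e, pair.backward)):
                fam, p0, p1, p2, sc = rate.kernel_params()
                fams[d] = fam
                pars[d] = (p0, p1, p2)
                scales[d] = sc
    terms = model.conductance_terms()
    cond_g = np.array([t.g_max for t in terms], dtype=float)
    cond_E = np.array([t.E_rev for t in terms], dtype=float)
    cond_foff = np.zeros(len(terms) + 1, dtype=np.int64)
    fstate, fpow, term_N, names = [], [], [], []
    for c, t in enumerate(terms):
        cond_foff[c + 1] = cond_foff[c] + len(t.factors)
        for (pi, s, w) in t.factors:
            fstate.append(int(pop_soff[pi]) + s)
            fpow.append(float(w))
        p0, _, w0 = t.factors[0]
        term_N.append(pops[p0].N / w0 if len(t.factors) > 1 or w0 != 1 else pops[p0].N)
        names.append(pops[p0].scheme.name)
    pk = PackedModel(
        pop_soff=pop_soff,
        pop_eoff=pop_eoff,
        esrc=esrc,
        edst=edst,
        fams=fams,
        pars=pars,
        scales=scales,
        N=np.array([pop.N for pop in pops], dtype=float),
        cond_g=cond_g,
        cond_E=cond_E,
        cond_foff=cond_foff,
        cond_fstate=np.array(fstate, dtype=np.int64),
        cond_fpow=np.array(fpow, dtype=float),
        term_N=np.array(term_N, dtype=float),
        open_idx=np.array(
            [pop_soff[p] + pop.scheme.open_state for p, pop in enumerate(pops)],
            dtype=np.int64,
        ),
        current_names=names,
    )
    try:
        model._packed = pk
    except AttributeError:
        pass
    return pk


# ---------------------------------------------------------------------------
# rate evaluation


@njit(cache=True, inline="always")
def _rate_value(fam, p0, p1, p2, V):
    if fam == 0:  # constant
        return p0
    elif fam == 1:  # linear over expm1: p0*(V-p1)/(1-exp(-(V-p1)/p2))
        u = V - p1
        if abs(u / p2) < 1e-7:
            return p0 * p2 * (1.0 + 0.5 * u / p2)
        return p0 * u / (1.0 - np.exp(-u / p2))
    elif fam == 2:  # exponential
        return p0 * np.exp((V - p1) / p2)
    else:  # sigmoid
        return p0 / (1.0 + np.exp(-(V - p1) / p2))


@njit(cache=True)
def _eval_rates(fams, pars, scales, V, out):
    for d in range(fams.shape[0]):
        out[d] = scales[d] * _rate_value(
            fams[d], pars[d, 0], pars[d, 1], pars[d, 2], V
        )


@njit(cache=True, inline="always")
def _stim(t, I_amp, I_t0, I_t1):
    if I_t0 <= t < I_t1:
        return I_amp
    return 0.0


@njit(cache=True, inline="always")
def _cond_fraction(x, cond_foff, cond_fstate, cond_fpow, c):
    g = 1.0
    for f in range(cond_foff[c], cond_foff[c + 1]):
        p = cond_fpow[f]
        xv = x[cond_fstate[f]]
        if p == 1.0:
            g *= xv
        else:
            g *= xv ** p
    return g


# ---------------------------------------------------------------------------
# diffusion-approximation kernel


@njit(cache=True)
def da_kernel(
    pop_soff,
    pop_eoff,
    esrc,
    edst,
    fams,
    pars,
    scales,
    Ninv,
    cond_g,
    cond_E,
    cond_foff,
    cond_fstate,
    cond_fpow,
    C_m,
    g_leak,
    E_leak,
    vclamp,
    V0,
    x,
    I_amp,
    I_t0,
    I_t1,
    dt,
    n_steps,
    stride,
    ss_mode,
    ss_v0,
    ss_dv,
    ss_tab,
    clip01,
    seed,
    rec_V,
    rec_open,
):
    """Euler-Maruyama integration of the coupled-particle DA.

    ``x`` is modified in place and holds the final state on return.
    Returns the step index at which the voltage diverged, or -1.
    One standard normal is drawn per transition pair per step.
    """
    np.random.seed(seed)
    P = pop_soff.shape[0] - 1
    S = x.shape[0]
    E = esrc.shape[0]
    C = cond_g.shape[0]
    V = V0
    r = np.empty(2 * E)
    dx = np.empty(S)
    ssx = np.empty(S)
    sqdt = np.sqrt(dt)
    if vclamp:
        _eval_rates(fams, pars, scales, V, r)
    if ss_mode:
        # steady-state fractions at the current voltage (table lookup)
        fi = (V - ss_v0) / ss_dv
        i0 = int(fi)
        if i0 < 0:
            i0 = 0
        elif i0 > ss_tab.shape[0] - 2:
            i0 = ss_tab.shape[0] - 2
        w = fi - i0
        for s in range(S):
            ssx[s] = (1.0 - w) * ss_tab[i0, s] + w * ss_tab[i0 + 1, s]
    for step in range(n_steps):
        t = step * dt
        if step % stride == 0:
            idx = step // stride
            rec_V[idx] = V
            for c in range(C):
                rec_open[idx, c] = _cond_fraction(
                    x, cond_foff, cond_fstate, cond_fpow, c
                )
        if not vclamp:
            _eval_rates(fams, pars, scales, V, r)
            if ss_mode:
                fi = (V - ss_v0) / ss_dv
                i0 = int(fi)
                if i0 < 0:
                    i0 = 0
                elif i0 > ss_tab.shape[0] - 2:
                    i0 = ss_tab.shape[0] - 2
                w = fi - i0
                for s in range(S):
                    ssx[s] = (1.0 - w) * ss_tab[i0, s] + w * ss_tab[i0 + 1, s]
        for s in range(S):
            dx[s] = 0.0
        for p in range(P):
            ninv = Ninv[p]
            for e in range(pop_eoff[p], pop_eoff[p + 1]):
                i = esrc[e]
                j = edst[e]
                a = r[e]
                b = r[E + e]
                net = (a * x[i] - b * x[j]) * dt  # deterministic flux i -> j
                if ss_mode:
                    wflux = a * ssx[i] + b * ssx[j]
                else:
                    wflux = a * x[i] + b * x[j]
                eta = np.random.normal()
                c_noise = np.sqrt(abs(wflux) * ninv) * sqdt * eta
                dx[i] += -net + c_noise
                dx[j] += net - c_noise
            # advance all but the redundant (last) state, then close the sum
            last = pop_soff[p + 1] - 1
            ssum = 0.0
            for s in range(pop_soff[p], last):
                xs = x[s] + dx[s]
                if clip01:
                    if xs < 0.0:
                        xs = 0.0
                    elif xs > 1.0:
                        xs = 1.0
                x[s] = xs
                ssum += xs
            xl = 1.0 - ssum
            if clip01:
                if xl < 0.0:
                    xl = 0.0
                elif xl > 1.0:
                    xl = 1.0
            x[last] = xl
        if not vclamp:
            I_ion = g_leak * (V - E_leak)
            for c in range(C):
                gf = _cond_fraction(x, cond_foff, cond_fstate, cond_fpow, c)
                I_ion += cond_g[c] * gf * (V - cond_E[c])
            V += dt * (_stim(t, I_amp, I_t0, I_t1) - I_ion) / C_m
            if not np.isfinite(V):
                return step
    idx = n_steps // stride
    if idx * stride == n_steps and idx < rec_V.shape[0]:
        rec_V[idx] = V
        for c in range(C):
            rec_open[idx, c] = _cond_fraction(x, cond_foff, cond_fstate, cond_fpow, c)
    return -1


# ---------------------------------------------------------------------------
# Markov-chain (number tracking) kernel


@njit(cache=True, inline="always")
def _total_rate(counts, r, esrc, edst, E):
    lam = 0.0
    for e in range(E):
        lam += counts[esrc[e]] * r[e] + counts[edst[e]] * r[E + e]
    return lam


@njit(cache=True)
def mc_kernel(
    pop_soff,
    pop_eoff,
    esrc,
    edst,
    fams,
    pars,
    scales,
    open_idx,
    g_pop,
    E_pop,
    Npop,
    C_m,
    g_leak,
    E_leak,
    vclamp,
    V0,
    counts,
    I_amp,
    I_t0,
    I_t1,
    dt,
    n_steps,
    stride,
    seed,
    rec_V,
    rec_open,
):
    """Exact number-tracking simulation of channel counts.

    Within each dt the rates are frozen at the current voltage; the
    effective rate lambda = sum_d counts[src_d] * rate_d sets
    exponential lifetimes; transitions are selected by inverting the
    cumulative transition probability with a single uniform draw.  The
    residual next-transition time is carried across steps.  ``counts``
    is modified in place.  Returns the diverged step index or -1.
    """
    np.random.seed(seed)
    P = pop_soff.shape[0] - 1
    E = esrc.shape[0]
    V = V0
    r = np.empty(2 * E)
    _eval_rates(fams, pars, scales, V, r)
    lam = _total_rate(counts, r, esrc, edst, E)
    if lam > 0.0:
        t_next = -np.log(np.random.random()) / lam
    else:
        t_next = np.inf
    for step in range(n_steps):
        t = step * dt
        if step % stride == 0:
            idx = step // stride
            rec_V[idx] = V
            for p in range(P):
                rec_open[idx, p] = counts[open_idx[p]]
        if not vclamp:
            # voltage changed last step: refresh rates, keep pending event
            _eval_rates(fams, pars, scales, V, r)
            lam = _total_rate(counts, r, esrc, edst, E)
            if not np.isfinite(t_next) and lam > 0.0:
                t_next = t - np.log(np.random.random()) / lam
        t_end = t + dt
        while t_next <= t_end:
            if lam <= 0.0:
                t_next = np.inf
                break
            u = np.random.random() * lam
            acc = 0.0
            chosen = -1
            lastpos = -1
            for d in range(2 * E):
                if d < E:
                    src = esrc[d]
                else:
                    src = edst[d - E]
                w = counts[src] * r[d]
                if w > 0.0:
                    lastpos = d
                    acc += w
                    if u <= acc:
                        chosen = d
                        break
            if chosen < 0:
                chosen = lastpos  # float rounding guard
            if chosen < 0:
                t_next = np.inf
                break
            if chosen < E:
                counts[esrc[chosen]] -= 1
                counts[edst[chosen]] += 1
            else:
                counts[edst[chosen - E]] -= 1
                counts[esrc[chosen - E]] += 1
            lam = _total_rate(counts, r, esrc, edst, E)
            if lam > 0.0:
                t_next = t_next - np.log(np.random.random()) / lam
            else:
                t_next = np.inf
        if not vclamp:
            I_ion = g_leak * (V - E_leak)
            for p in range(P):
                frac = counts[open_idx[p]] / Npop[p]
                I_ion += g_pop[p] * frac * (V - E_pop[p])
            V += dt * (_stim(t, I_amp, I_t0, I_t1) - I_ion) / C_m
            if not np.isfinite(V):
                return step
    idx = n_steps // stride
    if idx * stride == n_steps and idx < rec_V.shape[0]:
        rec_V[idx] = V
        for p in range(P):
            rec_open[idx, p] = counts[open_idx[p]]
    return -1
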