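"""Exact Markov-chain simulation by channel-number tracking.

Rather than following every channel, the engine tracks how many
channels occupy each aggregated state (a Gillespie-type algorithm
interleaved with Euler updates of the membrane equation).  Within each
membrane time step the rates are frozen at the current voltage; the
effective transition rate

    lambda = sum_i N_i * zeta_i,   zeta_i = sum_j alpha_ij

sets exponential lifetimes between transitions, and each transition is
selected with probability ``N_i alpha_j / lambda`` by inverting the
cumulative transition probability with one uniform draw.  The residual
next-transition time is carried across membrane steps.  Because rates
are frozen within dt, accuracy degrades for large dt exactly as it
does for the DA engine -- this is intended behaviour, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .kinetics import SchemeError, steady_state_fractions
from .models import MembraneModel
from .protocols import Protocol
from .trace import Trace
from .da_engine import _kernel_seed, _protocol_setup

__all__ = ["McState", "initial_counts", "mc_advance_step", "simulate_mc"]


@dataclass
class McState:
    """Counts per population, voltage, time, and the pending absolute
    next-transition time."""

    counts: list
    V: float
    t: float
    t_next: float = np.inf


def initial_counts(
    x: np.ndarray, N: int, rng: np.random.Generator | None = None, sample: bool = False
) -> np.ndarray:
    """Integer counts targeting fractions ``x``.

    Deterministic largest-remainder rounding by default (reproducible);
    ``sample=True`` draws from a multinomial instead.
    """
    x = np.asarray(x, dtype=float)
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    if sample:
        if rng is None:
            rng = np.random.default_rng()
        return rng.multinomial(N, x).astype(np.int64)
    base = np.floor(N * x).astype(np.int64)
    short = N - base.sum()
    if short > 0:
        remainder = N * x - base
        for idx in np.argsort(-remainder, kind="stable")[:short]:
            base[idx] += 1
    return base


def _directed_weights(model: MembraneModel, counts: list, V: float):
    """(weights, moves): per directed transition, ``N_src * rate`` and
    the (pop, src, dst) move it performs."""
    weights, moves = [], []
    for p_idx, pop in enumerate(model.populations):
        r = pop.scheme.pair_rates(V)
        for k, pair in enumerate(pop.scheme.pairs):
            weights.append(counts[p_idx][pair.i] * r[k, 0])
            moves.append((p_idx, pair.i, pair.j))
            weights.append(counts[p_idx][pair.j] * r[k, 1])
            moves.append((p_idx, pair.j, pair.i))
    return np.array(weights), moves


def mc_advance_step(
    state: McState,
    model: MembraneModel,
    dt: float,
    rng: np.random.Generator,
    I_stim: float = 0.0,
    voltage_clamp: bool = False,
) -> McState:
    """Advance one membrane time step (pure NumPy reference
    implementation of the number-tracking algorithm)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    counts = [c.copy() for c in state.counts]
    V, t = state.V, state.t
    w, moves = _directed_weights(model, counts, V)
    lam = w.sum()
    t_next = state.t_next
    if not np.isfinite(t_next) and lam > 0:
        t_next = t + rng.exponential(1.0 / lam)
    t_end = t + dt
    while t_next <= t_end:
        if lam <= 0:
            t_next = np.inf
            break
        u = rng.random() * lam
        cum = np.cumsum(w)
        d = int(np.searchsorted(cum, u))
        d = min(d, len(moves) - 1)
        p_idx, src, dst = moves[d]
        if counts[p_idx][src] <= 0:  # invariant trap: cannot leave empty state
            raise SchemeError("selected transition from an empty state")
        counts[p_idx][src] -= 1
        counts[p_idx][dst] += 1
        w, moves = _directed_weights(model, counts, V)
        lam = w.sum()
        t_next = t_next + rng.exponential(1.0 / lam) if lam > 0 else np.inf
    if not voltage_clamp:
        xs = [c / pop.N for c, pop in zip(counts, model.populations)]
        I_ion = model.ionic_current(xs, V)
        V = V + dt * (I_stim - I_ion) / model.C_m
    return McState(counts=counts, V=V, t=t_end, t_next=t_next)


def simulate_mc(
    model: MembraneModel,
    protocol: Protocol,
    dt: float,
    seed=0,
    record_stride: int = 1,
    x0: list | None = None,
    V0: float | None = None,
    sample_init: bool = False,
    backend: str = "numba",
) -> Trace:
    """Simulate the channel-count Markov chain under a protocol.

    Initial counts are derived from the protocol's equilibrium
    fractions by largest-remainder rounding (or multinomial sampling
    with ``sample_init=True``).  Voltage-clamp protocols hold V at the
    command value and skip the membrane update.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if model.conductances is not None:
        raise SchemeError("the MC engine requires standard per-population conductances")
    vclamp, V_init, x0, (I_amp, I_t0, I_t1) = _protocol_setup(model, protocol, x0, V0)
    rng = np.random.default_rng(np.random.SeedSequence((int(_kernel_seed(seed)), 1)))
    counts0 = [
        initial_counts(xi, pop.N, rng=rng, sample=sample_init)
        for xi, pop in zip(x0, model.populations)
    ]
    n_steps = int(round(protocol.total / dt))
    n_rec = n_steps // record_stride + 1
    pk = _kernels.pack_model(model)
    rec_V = np.empty(n_rec)
    rec_open = np.empty((n_rec, len(model.populations)))
    counts = (
        np.concatenate(counts0).astype(np.int64) if counts0 else np.zeros(0, np.int64)
    )

    if backend == "numba":
        div = _kernels.mc_kernel(
            pk.pop_soff, pk.pop_eoff, pk.esrc, pk.edst, pk.fams, pk.pars, pk.scales,
            pk.open_idx,
            np.array([p.g_max for p in model.populations]),
            np.array([p.E_rev for p in model.populations]),
            pk.N,
            model.C_m, model.g_leak, model.E_leak,
            vclamp, V_init, counts, I_amp, I_t0, I_t1,
            dt, n_steps, record_stride, _kernel_seed(seed),
            rec_V, rec_open,
        )
    elif backend == "python":
        div = _python_mc_loop(
            model, vclamp, V_init, counts0, I_amp, I_t0, I_t1,
            dt, n_steps, record_stride, seed, rec_V, rec_open,
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    diverged = div >= 0
    if diverged:
        keep = div // record_stride + 1
        rec_V, rec_open = rec_V[:keep], rec_open[:keep]
    t = np.arange(rec_V.size) * record_stride * dt
    return Trace(
        t=t,
        V=rec_V,
        open_count=rec_open,
        diverged=diverged,
        meta={
            "engine": "mc",
            "model": model.name,
            "protocol": protocol,
            "dt": dt,
            "seed": seed,
            "current_names": pk.current_names,
            "diverged_step": int(div) if diverged else None,
            "final_counts": counts,
        },
    )


def _python_mc_loop(
    model, vclamp, V_init, counts0, I_amp, I_t0, I_t1, dt, n_steps, stride,
    seed, rec_V, rec_open,
):
    rng = np.random.default_rng(seed)
    state = McState(counts=[c.copy() for c in counts0], V=V_init, t=0.0)

    def record(idx):
        rec_V[idx] = state.V
        for p_idx, pop in enumerate(model.populations):
            rec_open[idx, p_idx] = state.counts[p_idx][pop.scheme.open_state]

    for step in range(n_steps):
        t = step * dt
        if step % stride == 0:
            record(step // stride)
        I = I_amp if I_t0 <= t < I_t1 else 0.0
        state = mc_advance_step(
            state, model, dt, rng, I_stim=I, voltage_clamp=vclamp
        )
        if not np.isfinite(state.V):
            return step
    idx = n_steps // stride
    if idx * stride == n_steps and idx < rec_V.shape[0]:
        record(idx)
    return -1
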