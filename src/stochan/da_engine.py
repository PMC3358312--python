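"""Euler-Maruyama integration of the coupled-particle diffusion
approximation (DA).

The SDE integrated for every population is

    x(t + dt) = x(t) + A(V)^T x dt + sum_k S_col_k(x, V) sqrt(dt) eta_k

with one independent standard-normal ``eta_k`` per kinetic transition
pair (T draws per population per step, *not* S).  The redundant last
state of each population is eliminated: it is reconstructed as
``1 - sum(others)`` after every step, so the fractions sum to one to
machine precision over arbitrarily long runs.

Variants
--------
``exact``
    Noise coefficients evaluated at the instantaneous fractions (the
    method of record; no further approximation).
``steady_state``
    Noise coefficients evaluated at the equilibrium fractions
    ``x_inf(V)`` for the instantaneous voltage (the approximation used
    by earlier DA implementations; inaccurate whenever the voltage
    moves faster than the state variables).  The drift always uses the
    instantaneous fractions.
``uncoupled``
    Independent two-state particle SDEs with the open fraction taken
    as the product of particle-fraction powers; a comparison baseline
    that underestimates conductance fluctuations.

Fractions are never rounded or clipped to [0, 1] (set ``clip01=True``
to experiment with large time steps); square roots are taken of
absolute values so the noise terms stay real.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .kinetics import drift, noise_coefficients, steady_state_fractions
from .models import MembraneModel, uncoupled_membrane
from .protocols import CurrentPulse, FreeRun, Protocol, VoltageClampStep
from .trace import Trace

__all__ = [
    "DaState",
    "da_step",
    "simulate_da",
    "steady_state_fractions",
    "DA_VARIANTS",
]

DA_VARIANTS = ("exact", "steady_state", "uncoupled")

_SS_TABLE_CACHE: dict = {}


@dataclass
class DaState:
    """Instantaneous DA state: full fraction vector per population,
    voltage and time.  (The compiled kernels store the reduced
    representation; here the full vectors are kept for clarity.)"""

    x: list
    V: float
    t: float


def da_step(
    state: DaState,
    model: MembraneModel,
    dt: float,
    rng: np.random.Generator | None = None,
    variant: str = "exact",
    I_stim: float = 0.0,
    voltage_clamp: bool = False,
    eta: list | None = None,
) -> DaState:
    """One Euler-Maruyama step (pure NumPy reference implementation).

    ``eta`` may supply the standard-normal vector per population (one
    entry per transition pair, in pair order) for reproducible
    single-step checks; otherwise ``rng`` is used.
    """
    if variant not in ("exact", "steady_state"):
        raise ValueError(
            "da_step supports 'exact' and 'steady_state'; for the uncoupled "
            "variant transform the model with uncoupled_membrane() first"
        )
    if eta is None and rng is None:
        rng = np.random.default_rng()
    new_x = []
    for p_idx, pop in enumerate(model.populations):
        x = np.asarray(state.x[p_idx], dtype=float)
        mu = drift(pop.scheme, x, state.V)
        x_noise = (
            steady_state_fractions(pop.scheme, state.V)
            if variant == "steady_state"
            else x
        )
        S_mat = noise_coefficients(pop.scheme, x_noise, state.V, pop.N)
        e = (
            np.asarray(eta[p_idx], dtype=float)
            if eta is not None
            else rng.standard_normal(pop.scheme.n_pairs)
        )
        xn = x + mu * dt + np.sqrt(dt) * (S_mat @ e)
        xn[-1] = 1.0 - xn[:-1].sum()  # redundant-state elimination
        new_x.append(xn)
    if voltage_clamp:
        V = state.V
    else:
        I_ion = model.ionic_current(new_x, state.V)
        V = state.V + dt * (I_stim - I_ion) / model.C_m
    return DaState(x=new_x, V=V, t=state.t + dt)


def _ss_table(model: MembraneModel, v0: float, v1: float, dv: float) -> np.ndarray:
    """Concatenated steady-state fractions on a uniform voltage grid.
    Linear interpolation between rows preserves the unit sum exactly."""
    key = (tuple(id(p.scheme) for p in model.populations), v0, v1, dv)
    if key not in _SS_TABLE_CACHE:
        grid = np.arange(v0, v1 + 0.5 * dv, dv)
        S_tot = sum(p.scheme.n_states for p in model.populations)
        tab = np.empty((grid.size, S_tot))
        for gi, V in enumerate(grid):
            off = 0
            for pop in model.populations:
                s = pop.scheme.n_states
                tab[gi, off : off + s] = steady_state_fractions(pop.scheme, V)
                off += s
        _SS_TABLE_CACHE[key] = (grid[0], dv, tab)
    return _SS_TABLE_CACHE[key]


def _protocol_setup(model, protocol, x0, V0):
    """Common initial condition and stimulus unpacking."""
    from .models import resting_potential

    if isinstance(protocol, VoltageClampStep):
        vclamp = True
        V_init = protocol.V_command
        equil_V = protocol.V_hold
        stim = (0.0, 0.0, 0.0)
    elif isinstance(protocol, CurrentPulse):
        vclamp = False
        V_init = resting_potential(model) if V0 is None else V0
        equil_V = V_init
        stim = (protocol.amplitude, protocol.onset, protocol.onset + protocol.width)
    elif isinstance(protocol, FreeRun):
        vclamp = False
        V_init = resting_potential(model) if V0 is None else V0
        equil_V = V_init
        stim = (protocol.I_bias, 0.0, protocol.total)
    else:
        raise TypeError(f"unsupported protocol {protocol!r}")
    if V0 is not None and vclamp:
        V_init = V0
    if x0 is None:
        x0 = [steady_state_fractions(p.scheme, equil_V) for p in model.populations]
    return vclamp, V_init, x0, stim


def _kernel_seed(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def simulate_da(
    model: MembraneModel,
    protocol: Protocol,
    dt: float,
    seed=0,
    variant: str = "exact",
    record_stride: int = 1,
    x0: list | None = None,
    V0: float | None = None,
    clip01: bool = False,
    deterministic: bool = False,
    backend: str = "numba",
) -> Trace:
    """Simulate the DA SDE under a protocol and return a :class:`Trace`.

    ``deterministic=True`` integrates the drift only (the infinite-N
    limit).  ``record_stride`` subsamples the recorded grid.  The same
    seed always reproduces the same trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if variant not in DA_VARIANTS:
        raise ValueError(f"unknown DA variant {variant!r}")
    run_model = uncoupled_membrane(model) if variant == "uncoupled" else model
    vclamp, V_init, x0, (I_amp, I_t0, I_t1) = _protocol_setup(
        run_model, protocol, x0, V0
    )
    n_steps = int(round(protocol.total / dt))
    n_rec = n_steps // record_stride + 1
    pk = _kernels.pack_model(run_model)
    x = (
        np.concatenate([np.asarray(xi, dtype=float) for xi in x0])
        if x0
        else np.zeros(0)
    )
    Ninv = np.zeros(len(run_model.populations)) if deterministic else 1.0 / pk.N
    ss_mode = variant == "steady_state"
    if ss_mode:
        if vclamp:
            row = np.concatenate(
                [steady_state_fractions(p.scheme, V_init) for p in run_model.populations]
            )
            ss_v0, ss_dv, ss_tab = V_init - 1.0, 2.0, np.vstack([row, row])
        else:
            ss_v0, ss_dv, ss_tab = _ss_table(run_model, -150.0, 250.0, 0.05)
    else:
        ss_v0, ss_dv, ss_tab = 0.0, 1.0, np.zeros((2, x.size))
    rec_V = np.empty(n_rec)
    rec_open = np.empty((n_rec, pk.cond_g.size))

    if backend == "numba":
        div = _kernels.da_kernel(
            pk.pop_soff, pk.pop_eoff, pk.esrc, pk.edst, pk.fams, pk.pars, pk.scales,
            Ninv, pk.cond_g, pk.cond_E, pk.cond_foff, pk.cond_fstate, pk.cond_fpow,
            run_model.C_m, run_model.g_leak, run_model.E_leak,
            vclamp, V_init, x, I_amp, I_t0, I_t1,
            dt, n_steps, record_stride,
            ss_mode, ss_v0, ss_dv, ss_tab, clip01,
            _kernel_seed(seed),
            rec_V, rec_open,
        )
    elif backend == "python":
        div = _python_da_loop(
            run_model, vclamp, V_init, x0, I_amp, I_t0, I_t1, dt, n_steps,
            record_stride, variant if variant != "uncoupled" else "exact",
            deterministic, seed, rec_V, rec_open, pk,
        )
        x = None
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
        open_count=rec_open * pk.term_N,
        diverged=diverged,
        meta={
            "engine": "da",
            "variant": variant,
            "model": model.name,
            "protocol": protocol,
            "dt": dt,
            "seed": seed,
            "deterministic": deterministic,
            "current_names": pk.current_names,
            "diverged_step": int(div) if diverged else None,
            "final_state": x,
        },
    )


def _python_da_loop(
    model, vclamp, V_init, x0, I_amp, I_t0, I_t1, dt, n_steps, stride,
    variant, deterministic, seed, rec_V, rec_open, pk,
):
    """Reference loop over :func:`da_step` (slow; for validation)."""
    rng = np.random.default_rng(seed)
    state = DaState(x=[np.array(xi, dtype=float) for xi in x0], V=V_init, t=0.0)
    work = model
    if deterministic:
        work = replace_populations_inf(model)

    def record(idx):
        rec_V[idx] = state.V
        xs = np.concatenate(state.x)
        for c in range(pk.cond_g.size):
            g = 1.0
            for f in range(pk.cond_foff[c], pk.cond_foff[c + 1]):
                g *= xs[pk.cond_fstate[f]] ** pk.cond_fpow[f]
            rec_open[idx, c] = g

    for step in range(n_steps):
        t = step * dt
        if step % stride == 0:
            record(step // stride)
        I = I_amp if I_t0 <= t < I_t1 else 0.0
        eta = None
        if deterministic:
            eta = [np.zeros(p.scheme.n_pairs) for p in work.populations]
        state = da_step(
            state, work, dt, rng=rng, variant=variant, I_stim=I,
            voltage_clamp=vclamp, eta=eta,
        )
        if not np.isfinite(state.V):
            return step
    idx = n_steps // stride
    if idx * stride == n_steps and idx < rec_V.shape[0]:
        record(idx)
    return -1


def replace_populations_inf(model: MembraneModel) -> MembraneModel:
    """Copy of the model with astronomically many channels per
    population (noise amplitude ~ 1/sqrt(N) becomes negligible)."""
    pops = [replace(p, N=int(1e18)) for p in model.populations]
    return replace(model, populations=pops)
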