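"""Built-in channel schemes and membrane models.

Two single-compartment membrane models are provided:

* ``rb_membrane`` -- a mammalian node-of-Ranvier membrane: one
  fast-kinetics 8-state sodium channel population plus an ohmic leak
  whose reversal potential defines 0 mV.  Units: mV, ms, uS, nA, nF
  (C_m = 0.0189 nF = 18.9 pF, R = 7.372 MOhm, g_Na = 6.808 uS,
  E_Na = 144 mV).
* ``hh_membrane`` -- the stochastic Hodgkin-Huxley squid-axon membrane
  (voltages shifted so the resting potential is -65 mV).  Units: mV,
  ms, mS, uA, uF (C_m = 1 uF, g_Na = 120 mS, g_K = 36 mS,
  g_l = 0.3 mS, E_Na = 50 mV, E_K = -77 mV, E_l = -54.4 mV).

Channel schemes are generated from independent two-state gating
particles by :func:`particle_scheme`: a channel with three activation
(m) particles and one inactivation (h) particle aggregates to 8 states
and 10 transition pairs; four n particles give 5 states and 4 pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .kinetics import KineticScheme, SchemeError, TransitionPair, steady_state_fractions
from .rates import ExpRate, LinExpRate, RateFunction, SigmoidRate

__all__ = [
    "ParticleType",
    "particle_scheme",
    "hh_potassium_scheme",
    "hh_sodium_scheme",
    "rb_sodium_scheme",
    "ChannelPopulation",
    "ConductanceTerm",
    "MembraneModel",
    "rb_membrane",
    "hh_membrane",
    "uncoupled_membrane",
    "resting_potential",
    "HH_RATES",
    "RB_RATES",
    "RB_CONSTANTS",
    "HH_CONSTANTS",
]

# ---------------------------------------------------------------------------
# rate constants (mV, ms^-1)

HH_RATES = {
    "alpha_n": LinExpRate(a=0.01, vh=-55.0, k=10.0),
    "beta_n": ExpRate(A=0.125, vh=-65.0, k=-80.0),
    "alpha_m": LinExpRate(a=0.1, vh=-40.0, k=10.0),
    "beta_m": ExpRate(A=4.0, vh=-65.0, k=-18.0),
    "alpha_h": ExpRate(A=0.07, vh=-65.0, k=-20.0),
    "beta_h": SigmoidRate(A=1.0, vh=-35.0, k=10.0),
}

# node-of-Ranvier sodium kinetics (leak reversal defines 0 mV)
RB_RATES = {
    "alpha_m": LinExpRate(a=1.872, vh=25.41, k=6.06),
    "beta_m": LinExpRate(a=-3.973, vh=21.001, k=-9.41),
    "alpha_h": LinExpRate(a=-0.549, vh=-27.74, k=-9.06),
    "beta_h": SigmoidRate(A=22.57, vh=56.0, k=12.5),
}

RB_CONSTANTS = {
    "C_m": 0.0189,  # nF (18.9 pF)
    "R": 7.372,  # MOhm
    "g_Na": 6.808,  # uS
    "E_Na": 144.0,  # mV
    "E_leak": 0.0,  # mV (voltage shifted so leak reversal is 0)
}

HH_CONSTANTS = {
    "C_m": 1.0,  # uF
    "g_Na": 120.0,  # mS
    "g_K": 36.0,  # mS
    "g_l": 0.3,  # mS
    "E_Na": 50.0,  # mV
    "E_K": -77.0,  # mV
    "E_l": -54.4,  # mV
}


# ---------------------------------------------------------------------------
# particle combinatorics -> aggregated multi-state scheme


@dataclass(frozen=True)
class ParticleType:
    """An independent two-state gating particle type."""

    name: str
    multiplicity: int
    alpha: RateFunction  # resting -> active
    beta: RateFunction  # active -> resting


def particle_scheme(particles: list[ParticleType], name: str = "channel") -> KineticScheme:
    """Aggregate independent gating particles into a multi-state scheme.

    States enumerate all combinations of active-particle counts
    (``0..multiplicity`` per type, first type varying fastest); a state
    with ``c`` active particles of a type converts at rate
    ``(multiplicity - c) * alpha`` upward and ``c * beta`` downward.
    The open state has every particle active (the last index).
    """
    if not particles:
        raise SchemeError("need at least one particle type")
    dims = [p.multiplicity + 1 for p in particles]
    strides = np.concatenate([[1], np.cumprod(dims[:-1])]).astype(int)
    n_states = int(np.prod(dims))

    def index(counts):
        return int(np.dot(counts, strides))

    names = [None] * n_states
    for counts in itertools.product(*(range(d) for d in dims)):
        names[index(counts)] = "".join(
            f"{p.name}{c}" for p, c in zip(particles, counts)
        )

    pairs = []
    for counts in itertools.product(*(range(d) for d in dims)):
        s = index(counts)
        for k, p in enumerate(particles):
            c = counts[k]
            if c < p.multiplicity:
                t = s + strides[k]
                pairs.append(
                    TransitionPair(
                        i=s,
                        j=t,
                        forward=p.alpha.scaled(p.multiplicity - c),
                        backward=p.beta.scaled(c + 1),
                    )
                )
    return KineticScheme(
        n_states=n_states,
        pairs=pairs,
        open_state=n_states - 1,
        name=name,
        state_names=names,
        particles=list(particles),
    )


def hh_potassium_scheme() -> KineticScheme:
    """HH potassium channel: 4 identical n particles -> 5-state chain,
    forward rates (4a, 3a, 2a, a) and backward (b, 2b, 3b, 4b)."""
    return particle_scheme(
        [ParticleType("n", 4, HH_RATES["alpha_n"], HH_RATES["beta_n"])],
        name="hh_k",
    )


def hh_sodium_scheme() -> KineticScheme:
    """HH sodium channel: 3 m particles x 1 h particle -> 8 states,
    10 transition pairs; open state m3h1."""
    return particle_scheme(
        [
            ParticleType("m", 3, HH_RATES["alpha_m"], HH_RATES["beta_m"]),
            ParticleType("h", 1, HH_RATES["alpha_h"], HH_RATES["beta_h"]),
        ],
        name="hh_na",
    )


def rb_sodium_scheme() -> KineticScheme:
    """Node-of-Ranvier sodium channel: same 8-state / 10-pair topology as
    the HH sodium scheme, with fast mammalian-node rate functions."""
    return particle_scheme(
        [
            ParticleType("m", 3, RB_RATES["alpha_m"], RB_RATES["beta_m"]),
            ParticleType("h", 1, RB_RATES["alpha_h"], RB_RATES["beta_h"]),
        ],
        name="rb_na",
    )


# ---------------------------------------------------------------------------
# membrane models


@dataclass
class ChannelPopulation:
    """A scheme bound to N channels with a maximal conductance and
    reversal potential (conductance = g_max * open-state fraction)."""

    scheme: KineticScheme
    N: int
    g_max: float
    E_rev: float

    def __post_init__(self):
        if self.N < 1:
            raise SchemeError("population needs N >= 1 channels")
        if self.g_max < 0:
            raise SchemeError("g_max must be nonnegative")


@dataclass(frozen=True)
class ConductanceTerm:
    """One ionic-current term: ``g_max * prod(x[state]^power) * (V - E_rev)``.

    ``factors`` is a list of ``(population_index, local_state, power)``.
    Ordinary populations use a single factor (their open state, power 1);
    the uncoupled-particle variant uses products of particle fractions.
    """

    g_max: float
    E_rev: float
    factors: tuple


@dataclass
class MembraneModel:
    """Single-compartment membrane: C_m dV/dt = -I_ion - I_leak + I_stim.

    Units are whatever consistent set the model declares (see module
    docstring); voltages are always mV and time ms.
    """

    C_m: float
    g_leak: float
    E_leak: float
    populations: list[ChannelPopulation]
    name: str = "membrane"
    conductances: list[ConductanceTerm] | None = field(default=None)

    def __post_init__(self):
        if self.C_m <= 0:
            raise SchemeError("C_m must be positive")
        if self.g_leak <= 0:
            raise SchemeError("leak conductance must be positive")

    def conductance_terms(self) -> list[ConductanceTerm]:
        if self.conductances is not None:
            return self.conductances
        return [
            ConductanceTerm(
                g_max=pop.g_max,
                E_rev=pop.E_rev,
                factors=((p_idx, pop.scheme.open_state, 1),),
            )
            for p_idx, pop in enumerate(self.populations)
        ]

    def ionic_current(self, x_per_pop: list[np.ndarray], V: float) -> float:
        """Total ionic current (leak + channels) at state fractions
        ``x_per_pop`` and voltage ``V``; positive = outward."""
        I = self.g_leak * (V - self.E_leak)
        for term in self.conductance_terms():
            g = term.g_max
            for (p, s, w) in term.factors:
                g = g * x_per_pop[p][s] ** w
            I += g * (V - term.E_rev)
        return I


def rb_membrane(N_Na: int = 1000) -> MembraneModel:
    """Node-of-Ranvier membrane with ``N_Na`` stochastic sodium channels.

    Stimulus currents are in nA; the threshold-level 100 us pulse of
    ~5.8 nA depolarises the 18.9 pF membrane by ~30 mV.
    """
    c = RB_CONSTANTS
    return MembraneModel(
        C_m=c["C_m"],
        g_leak=1.0 / c["R"],
        E_leak=c["E_leak"],
        populations=[
            ChannelPopulation(rb_sodium_scheme(), N_Na, c["g_Na"], c["E_Na"])
        ],
        name="rb",
    )


def hh_membrane(N_Na: int = 3000, N_K: int | None = None) -> MembraneModel:
    """Stochastic Hodgkin-Huxley membrane.  ``N_K`` defaults to
    ``0.3 * N_Na`` (rounded), the benchmark channel-density ratio."""
    if N_K is None:
        N_K = int(round(0.3 * N_Na))
    c = HH_CONSTANTS
    return MembraneModel(
        C_m=c["C_m"],
        g_leak=c["g_l"],
        E_leak=c["E_l"],
        populations=[
            ChannelPopulation(hh_sodium_scheme(), N_Na, c["g_Na"], c["E_Na"]),
            ChannelPopulation(hh_potassium_scheme(), N_K, c["g_K"], c["E_K"]),
        ],
        name="hh",
    )


def uncoupled_membrane(model: MembraneModel) -> MembraneModel:
    """Rewrite a membrane model for the uncoupled-particle DA baseline.

    Every population built from gating particles is replaced by one
    two-state population per particle type (particle count =
    multiplicity x N) and a conductance term taking the product of
    active-fraction powers.  This is the diffusion limit of simulating
    every gating particle as an independent Markov chain and
    multiplying fractions; it underestimates the conductance variance
    of the true coupled channel.
    """
    new_pops: list[ChannelPopulation] = []
    terms: list[ConductanceTerm] = []
    for pop in model.populations:
        parts = pop.scheme.particles
        if parts is None:
            raise SchemeError(
                f"population {pop.scheme.name!r} was not built from particles; "
                "the uncoupled variant is undefined for it"
            )
        factors = []
        for p in parts:
            scheme = KineticScheme(
                n_states=2,
                pairs=[TransitionPair(0, 1, p.alpha, p.beta)],
                open_state=1,
                name=f"{pop.scheme.name}_{p.name}",
            )
            new_pops.append(
                ChannelPopulation(scheme, pop.N * p.multiplicity, 0.0, pop.E_rev)
            )
            factors.append((len(new_pops) - 1, 1, p.multiplicity))
        terms.append(
            ConductanceTerm(g_max=pop.g_max, E_rev=pop.E_rev, factors=tuple(factors))
        )
    return MembraneModel(
        C_m=model.C_m,
        g_leak=model.g_leak,
        E_leak=model.E_leak,
        populations=new_pops,
        name=model.name + "_uncoupled",
        conductances=terms,
    )


def resting_potential(
    model: MembraneModel, v_min: float = -100.0, v_max: float = 60.0
) -> float:
    """Deterministic resting potential: the zero of the steady-state
    current-voltage relation nearest the leak reversal potential."""

    def i_ss(V: float) -> float:
        xs = [steady_state_fractions(p.scheme, V) for p in model.populations]
        return model.ionic_current(xs, V)

    grid = np.linspace(v_min, v_max, 161)
    vals = np.array([i_ss(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        raise SchemeError("no resting potential found in bracket")
    # root nearest the leak reversal potential
    best = min(
        sign_change, key=lambda i: abs(0.5 * (grid[i] + grid[i + 1]) - model.E_leak)
    )
    return brentq(i_ss, grid[best], grid[best + 1], xtol=1e-10)
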