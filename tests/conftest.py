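import numpy as np
import pytest

from stochan.kinetics import KineticScheme, TransitionPair
from stochan.models import (
    ChannelPopulation,
    MembraneModel,
    hh_potassium_scheme,
    hh_sodium_scheme,
    rb_sodium_scheme,
)
from stochan.rates import ConstantRate


def two_state(alpha: float, beta: float) -> KineticScheme:
    """Closed <-> open with constant rates."""
    return KineticScheme(
        n_states=2,
        pairs=[TransitionPair(0, 1, ConstantRate(value=alpha), ConstantRate(value=beta))],
        open_state=1,
        name=f"two_state_{alpha}_{beta}",
    )


def random_scheme(rng: np.random.Generator, max_states: int = 8, max_pairs: int = 12):
    """Connected random scheme with constant rates (spanning tree plus
    extra random edges)."""
    S = int(rng.integers(2, max_states + 1))
    edges = set()
    order = rng.permutation(S)
    for a, b in zip(order[:-1], order[1:]):  # spanning tree: connected
        edges.add((min(a, b), max(a, b)))
    max_extra = S * (S - 1) // 2
    n_extra = int(rng.integers(0, max(1, min(max_pairs, max_extra) - len(edges) + 1)))
    while len(edges) < min(len(edges) + n_extra, max_pairs, max_extra):
        a, b = rng.choice(S, size=2, replace=False)
        edges.add((min(a, b), max(a, b)))
    pairs = [
        TransitionPair(
            int(i), int(j),
            ConstantRate(value=float(rng.uniform(0.05, 5.0))),
            ConstantRate(value=float(rng.uniform(0.05, 5.0))),
        )
        for i, j in sorted(edges)
    ]
    return KineticScheme(
        n_states=S, pairs=pairs, open_state=S - 1, name="random"
    )


@pytest.fixture(scope="session")
def k_scheme():
    return hh_potassium_scheme()


@pytest.fixture(scope="session")
def na_scheme():
    return hh_sodium_scheme()


@pytest.fixture(scope="session")
def rb_scheme():
    return rb_sodium_scheme()


@pytest.fixture(scope="session")
def k_clamp_model():
    """300 HH potassium channels under voltage clamp (negligible leak so
    the clamp protocol is the only driver)."""
    return MembraneModel(
        C_m=1.0,
        g_leak=1e-9,
        E_leak=0.0,
        populations=[ChannelPopulation(hh_potassium_scheme(), 300, 1.0, -77.0)],
        name="k_clamp",
    )
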