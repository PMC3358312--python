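"""Kinetic schemes and the matrices of the coupled-particle diffusion
approximation.

A kinetic scheme is a graph: vertices are aggregated channel states,
edges are *transition pairs* carrying a forward rate ``alpha_ij(V)``
(from the lower-indexed state ``i`` to ``j``) and a backward rate
``alpha_ji(V)``.  From the scheme alone this module derives

* the rate matrix ``A`` (off-diagonal ``A[i, j] = alpha_ij``, diagonal
  minus the row sum -- a weighted graph Laplacian transpose),
* the deterministic drift ``A^T x`` of the state fractions,
* the diffusion matrix ``D`` of the channel-count Langevin equation,
* the sparse S x T noise-coefficient matrix ``S`` with one column per
  transition pair, satisfying ``S @ S.T == D`` (an incidence-matrix
  generalisation); ``S`` is the closed-form matrix square root that
  makes the diffusion approximation cheap for arbitrary schemes.

Conventions: state fractions ``x`` sum to 1; they are *not* clipped to
[0, 1] (transient excursions are part of the method; the square roots in
``S`` are taken of absolute values so coefficients stay real).  Each
noise column enters its pair's lower-indexed state with ``+`` sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .rates import RateFunction

__all__ = [
    "SchemeError",
    "TransitionPair",
    "KineticScheme",
    "rate_matrix",
    "drift",
    "diffusion_matrix",
    "noise_coefficients",
    "steady_state_fractions",
]


class SchemeError(ValueError):
    """Invalid kinetic scheme or rate evaluation."""


@dataclass(frozen=True)
class TransitionPair:
    """An edge of the scheme: states ``i < j`` with rates
    ``forward`` (i -> j) and ``backward`` (j -> i)."""

    i: int
    j: int
    forward: RateFunction
    backward: RateFunction

    def __post_init__(self):
        if self.i == self.j:
            raise SchemeError(f"transition pair connects state {self.i} to itself")
        if self.i > self.j:
            # canonical ordering: i < j, swapping rates accordingly
            i, j = self.j, self.i
            f, b = self.backward, self.forward
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)
            object.__setattr__(self, "forward", f)
            object.__setattr__(self, "backward", b)


@dataclass
class KineticScheme:
    """States plus transition pairs of one channel type.

    Parameters
    ----------
    n_states:
        Number of aggregated states S >= 2.
    pairs:
        Ordered transition pairs; their order fixes the noise-column
        order of :func:`noise_coefficients`.
    open_state:
        Index of the conducting state.
    name:
        Label used in traces and metadata.
    state_names:
        Optional human-readable state labels.
    particles:
        Optional metadata set by :func:`stochan.models.particle_scheme`:
        list of ``(name, multiplicity, alpha, beta)`` describing the
        independent gating particles the scheme was built from.  Needed
        only by the uncoupled-DA comparison variant.
    """

    n_states: int
    pairs: list[TransitionPair]
    open_state: int
    name: str = "scheme"
    state_names: list[str] | None = None
    particles: list | None = field(default=None, repr=False)

    def __post_init__(self):
        S = self.n_states
        if S < 2:
            raise SchemeError("a kinetic scheme needs at least 2 states")
        if not 0 <= self.open_state < S:
            raise SchemeError("open_state out of range")
        seen = set()
        for p in self.pairs:
            if p.j >= S:
                raise SchemeError(f"pair ({p.i},{p.j}) references state >= {S}")
            key = (p.i, p.j)
            if key in seen:
                raise SchemeError(f"duplicate transition pair {key}")
            seen.add(key)
        if not self._connected():
            warnings.warn(
                f"scheme {self.name!r}: transition graph is not connected; "
                "steady state is not unique",
                stacklevel=2,
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def _connected(self) -> bool:
        adj = [[] for _ in range(self.n_states)]
        for p in self.pairs:
            adj[p.i].append(p.j)
            adj[p.j].append(p.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_states

    def pair_rates(self, V: float) -> np.ndarray:
        """(T, 2) array of (forward, backward) rates at voltage ``V``."""
        out = np.empty((self.n_pairs, 2))
        for k, p in enumerate(self.pairs):
            out[k, 0] = p.forward(V)
            out[k, 1] = p.backward(V)
        if np.any(out < 0) or not np.all(np.isfinite(out)):
            raise SchemeError(
                f"scheme {self.name!r}: negative or non-finite rate at V={V} mV"
            )
        return out


def rate_matrix(scheme: KineticScheme, V: float) -> np.ndarray:
    """S x S rate matrix: ``A[i, j] = alpha_ij(V)`` for connected pairs,
    diagonal set so every row sums to zero."""
    S = scheme.n_states
    A = np.zeros((S, S))
    r = scheme.pair_rates(V)
    for k, p in enumerate(scheme.pairs):
        A[p.i, p.j] = r[k, 0]
        A[p.j, p.i] = r[k, 1]
    A[np.diag_indices(S)] = -A.sum(axis=1)
    return A


def drift(scheme: KineticScheme, x: np.ndarray, V: float) -> np.ndarray:
    """Deterministic part of the fraction dynamics,
    ``dx_i/dt = sum_j (alpha_ji x_j - alpha_ij x_i)`` (== ``A^T x``).

    Built edge-by-edge so conservation holds exactly: each pair moves
    probability between its two states only.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != scheme.n_states:
        raise SchemeError(
            f"state vector length {x.shape[-1]} != n_states {scheme.n_states}"
        )
    r = scheme.pair_rates(V)
    dx = np.zeros_like(x)
    for k, p in enumerate(scheme.pairs):
        net = r[k, 0] * x[..., p.i] - r[k, 1] * x[..., p.j]  # net flux i -> j
        dx[..., p.i] -= net
        dx[..., p.j] += net
    return dx


def diffusion_matrix(
    scheme: KineticScheme, x: np.ndarray, V: float, N: float
) -> np.ndarray:
    """S x S diffusion matrix ``D`` of the channel-count Langevin equation.

    ``D[i, i] = (1/N) sum_{j~i} (alpha_ij x_i + alpha_ji x_j)`` and
    ``D[i, j] = -(1/N)(alpha_ij x_i + alpha_ji x_j)`` for connected
    ``i != j``; zero otherwise.  Symmetric, zero row sums, positive
    semi-definite for ``x >= 0``.
    """
    if N < 1:
        raise SchemeError("channel count N must be >= 1")
    x = np.asarray(x, dtype=float)
    S = scheme.n_states
    D = np.zeros((S, S))
    r = scheme.pair_rates(V)
    for k, p in enumerate(scheme.pairs):
        w = (r[k, 0] * x[p.i] + r[k, 1] * x[p.j]) / N
        D[p.i, p.i] += w
        D[p.j, p.j] += w
        D[p.i, p.j] -= w
        D[p.j, p.i] -= w
    return D


def noise_coefficients(
    scheme: KineticScheme, x: np.ndarray, V: float, N: float
) -> np.ndarray:
    """Sparse S x T noise-coefficient matrix ``S_mat``.

    Column k (transition pair ``(i, j)``) holds
    ``c_k = sqrt(|alpha_ij x_i + alpha_ji x_j| / N)`` at row ``i`` and
    ``-c_k`` at row ``j``; all other entries vanish.  One independent
    standard normal per column drives the SDE, so the number of noise
    terms equals the number of transition pairs, not states.
    """
    if N < 1:
        raise SchemeError("channel count N must be >= 1")
    x = np.asarray(x, dtype=float)
    S = scheme.n_states
    T = scheme.n_pairs
    out = np.zeros((S, T))
    r = scheme.pair_rates(V)
    for k, p in enumerate(scheme.pairs):
        c = np.sqrt(np.abs(r[k, 0] * x[p.i] + r[k, 1] * x[p.j]) / N)
        out[p.i, k] = c
        out[p.j, k] = -c
    return out


def steady_state_fractions(scheme: KineticScheme, V: float) -> np.ndarray:
    """Equilibrium state fractions: the normalised nullspace of ``A^T``.

    Raises :class:`SchemeError` if the nullspace is not one-dimensional
    (disconnected scheme).
    """
    A = rate_matrix(scheme, V)
    ns = null_space(A.T)
    if ns.shape[1] != 1:
        raise SchemeError(
            f"scheme {scheme.name!r}: steady state not unique "
            f"(nullspace dimension {ns.shape[1]})"
        )
    v = ns[:, 0]
    v = v / v.sum()
    # a proper CTMC equilibrium is nonnegative; clip away -0.0 noise
    v[np.abs(v) < 1e-15] = np.abs(v[np.abs(v) < 1e-15])
    return v
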