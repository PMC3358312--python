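"""Voltage-dependent transition-rate functions.

All rates are in ms^-1 and voltages in mV, package-wide.  Three named
functional families cover the Hodgkin-Huxley and node-of-Ranvier rate
expressions:

``linexp``
    ``a * (V - vh) / (1 - exp(-(V - vh) / k))`` -- the "linear over
    expm1" form of the HH alpha_m / alpha_n rates.  The removable
    singularity at ``V == vh`` is evaluated by its analytic limit
    ``a * k``.  The rate is nonnegative for all V whenever ``a`` and
    ``k`` share a sign.
``exp``
    ``A * exp((V - vh) / k)``.
``sigmoid``
    ``A / (1 + exp(-(V - vh) / k))``.

Every rate object carries an integer multiplicity ``scale`` so that
aggregated-scheme rates such as ``4 * alpha_n`` remain members of a named
family (required by the compiled simulation kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = [
    "RateFunction",
    "ConstantRate",
    "LinExpRate",
    "ExpRate",
    "SigmoidRate",
    "CustomRate",
    "FAMILY_CODES",
]

# integer codes shared with the numba kernels
FAMILY_CODES = {"constant": 0, "linexp": 1, "exp": 2, "sigmoid": 3}

# relative distance from the singular voltage below which the series
# limit of the linexp family is used
_SINGULAR_TOL = 1e-7


@dataclass(frozen=True)
class RateFunction:
    """Base class: a callable mapping voltage (mV) to a rate (ms^-1)."""

    scale: float = 1.0

    family: str = ""  # overridden by subclasses

    def __call__(self, V):  # pragma: no cover - abstract
        raise NotImplementedError

    def scaled(self, factor: float) -> "RateFunction":
        """Return a copy multiplied by ``factor`` (e.g. a multiplicity)."""
        return replace(self, scale=self.scale * factor)

    def kernel_params(self) -> tuple[int, float, float, float, float]:
        """``(family_code, p0, p1, p2, scale)`` encoding for the kernels."""
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantRate(RateFunction):
    value: float = 0.0
    family: str = "constant"

    def __call__(self, V):
        v = np.asarray(V, dtype=float)
        out = np.full_like(v, self.scale * self.value)
        return out if out.ndim else float(out)

    def kernel_params(self):
        return (0, self.value, 0.0, 0.0, self.scale)


@dataclass(frozen=True)
class LinExpRate(RateFunction):
    """``scale * a * (V - vh) / (1 - exp(-(V - vh) / k))``."""

    a: float = 1.0
    vh: float = 0.0
    k: float = 1.0
    family: str = "linexp"

    def __call__(self, V):
        v = np.asarray(V, dtype=float)
        u = v - self.vh
        near = np.abs(u / self.k) < _SINGULAR_TOL
        # series limit a*k*(1 + u/(2k) + ...) at the removable singularity
        safe_u = np.where(near, 1.0, u)
        out = np.where(
            near,
            self.a * self.k * (1.0 + 0.5 * u / self.k),
            self.a * safe_u / (-np.expm1(-safe_u / self.k)),
        )
        out = self.scale * out
        return out if out.ndim else float(out)

    def kernel_params(self):
        return (1, self.a, self.vh, self.k, self.scale)


@dataclass(frozen=True)
class ExpRate(RateFunction):
    """``scale * A * exp((V - vh) / k)``."""

    A: float = 1.0
    vh: float = 0.0
    k: float = 1.0
    family: str = "exp"

    def __call__(self, V):
        v = np.asarray(V, dtype=float)
        out = self.scale * self.A * np.exp((v - self.vh) / self.k)
        return out if out.ndim else float(out)

    def kernel_params(self):
        return (2, self.A, self.vh, self.k, self.scale)


@dataclass(frozen=True)
class SigmoidRate(RateFunction):
    """``scale * A / (1 + exp(-(V - vh) / k))``."""

    A: float = 1.0
    vh: float = 0.0
    k: float = 1.0
    family: str = "sigmoid"

    def __call__(self, V):
        v = np.asarray(V, dtype=float)
        out = self.scale * self.A / (1.0 + np.exp(-(v - self.vh) / self.k))
        return out if out.ndim else float(out)

    def kernel_params(self):
        return (3, self.A, self.vh, self.k, self.scale)


@dataclass(frozen=True)
class CustomRate(RateFunction):
    """Wrap an arbitrary callable.  Usable only on the python backend;
    the compiled kernels require one of the named families."""

    func: Callable[[float], float] = None
    family: str = "custom"

    def __call__(self, V):
        v = np.asarray(V, dtype=float)
        out = self.scale * np.asarray(self.func(v), dtype=float)
        return out if out.ndim else float(out)

    def kernel_params(self):
        raise TypeError(
            "custom rate functions cannot be compiled; use a named family "
            "(constant/linexp/exp/sigmoid) or the python backend"
        )
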