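"""Trace containers for simulation output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "EnsembleStats"]


@dataclass
class Trace:
    """One simulated trajectory.

    Attributes
    ----------
    t:
        Recorded time grid (ms).
    V:
        Membrane (or command) voltage at each recorded point (mV).
    open_count:
        ``(n_rec, n_currents)`` open-channel numbers per conductance
        term: integer-valued for the Markov-chain engine, real-valued
        (fraction x N) for the diffusion approximation.
    diverged:
        True if the voltage left the finite range and the run was
        terminated early (arrays are truncated at the last valid point).
    meta:
        Engine, model, protocol, dt, seed and variant bookkeeping.
    """

    t: np.ndarray
    V: np.ndarray
    open_count: np.ndarray
    diverged: bool = False
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t, "V": self.V}
        names = self.meta.get("current_names")
        for k in range(self.open_count.shape[1]):
            label = names[k] if names else f"open_{k}"
            cols[label] = self.open_count[:, k]
        return pd.DataFrame(cols)


@dataclass
class EnsembleStats:
    """Per-time-point mean and (unbiased) variance of an observable over
    an ensemble of sweeps, accumulated in a streaming fashion."""

    t: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    n_sweeps: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "mean": self.mean, "var": self.var})


class _Welford:
    """Streaming mean/variance accumulator over sweeps (vector valued)."""

    def __init__(self):
        self.n = 0
        self.mean = None
        self.m2 = None

    def add(self, x: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        if self.mean is None:
            self.mean = np.zeros_like(x)
            self.m2 = np.zeros_like(x)
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            raise ValueError("need >= 2 sweeps for a variance")
        return self.m2 / (self.n - 1)
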