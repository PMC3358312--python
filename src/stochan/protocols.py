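"""Stimulation protocols.

Three protocol kinds drive the engines:

* :class:`VoltageClampStep` -- channels equilibrated at a holding
  voltage, then the command voltage is applied instantaneously at t = 0
  and held; the membrane equation is bypassed.
* :class:`CurrentPulse` -- current clamp with a single rectangular
  stimulus pulse.
* :class:`FreeRun` -- current clamp with a constant (default zero) bias
  current; used for spontaneous-firing runs.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Protocol", "VoltageClampStep", "CurrentPulse", "FreeRun"]


@dataclass(frozen=True)
class Protocol:
    total: float  # ms

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("protocol duration must be positive")


@dataclass(frozen=True)
class VoltageClampStep(Protocol):
    """Hold at ``V_hold`` (initial condition = steady state there), then
    clamp at ``V_command`` for ``total`` ms."""

    V_hold: float = -90.0
    V_command: float = 70.0


@dataclass(frozen=True)
class CurrentPulse(Protocol):
    """Rectangular current pulse of ``amplitude`` (model current units)
    starting at ``onset`` for ``width`` ms, inside a ``total`` ms run."""

    amplitude: float = 0.0
    onset: float = 0.0
    width: float = 0.1

    def __post_init__(self):
        super().__post_init__()
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if self.onset < 0 or self.onset + self.width > self.total:
            raise ValueError("pulse must lie inside the run window")


@dataclass(frozen=True)
class FreeRun(Protocol):
    """Current clamp with constant bias current (default 0)."""

    I_bias: float = 0.0
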