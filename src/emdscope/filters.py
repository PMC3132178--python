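"""Recursive first-order temporal filters.

All temporal dynamics in the model are built from first-order low-pass
filters discretised with the exact exponential update

    y_t = y_{t-1} + alpha * (x_t - y_{t-1}),   alpha = 1 - exp(-dt / tau),

which matches the continuous-time impulse response at the sample points for
any step size.  The high-pass is implemented as identity minus low-pass, so
LP and HP are exactly complementary at every step (``x = LP(x) + HP(x)``).

Two equivalent surfaces are provided: per-step scalar/array functions
operating on an explicit :class:`FilterState` (convenient for unit tests and
small simulations), and streaming chunk processors built on
:func:`scipy.signal.lfilter` (used by the simulation engine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "FilterState",
    "alpha_for",
    "lowpass_step",
    "highpass_step",
    "lmc_bandpass_step",
    "StreamingLowpass",
    "StreamingHighpass",
    "StreamingBandpass",
]


def alpha_for(tau: float, dt: float) -> float:
    """Smoothing coefficient of the exponential low-pass update.

    ``tau <= 0`` degenerates to a pass-through (alpha = 1), which is the
    correct limit for an adapted high-pass with vanishing time constant.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau <= 0:
        return 1.0
    return 1.0 - float(np.exp(-dt / tau))


@dataclass
class FilterState:
    """State of one first-order stage: last output value(s) and tau."""

    y_prev: float | np.ndarray | None
    tau: float

    def ensure(self, x) -> None:
        if self.y_prev is None:
            # steady-state initialisation: no transient for constant input
            self.y_prev = np.array(x, dtype=float) if np.ndim(x) else float(x)


def lowpass_step(state: FilterState, x, dt: float):
    """One step of the recursive low-pass; updates ``state`` in place."""
    state.ensure(x)
    a = alpha_for(state.tau, dt)
    y = state.y_prev + a * (np.asarray(x, dtype=float) - state.y_prev)
    state.y_prev = y
    return y


def highpass_step(state: FilterState, x, dt: float):
    """One step of the complementary high-pass: ``y = x - LP(x)``."""
    return np.asarray(x, dtype=float) - lowpass_step(state, x, dt)


def lmc_bandpass_step(states: tuple[FilterState, FilterState], x, dt: float):
    """LMC band-pass: low-pass (tau_L) followed by high-pass (tau_H)."""
    lp_state, hp_state = states
    y = lowpass_step(lp_state, x, dt)
    return highpass_step(hp_state, y, dt)


class StreamingLowpass:
    """Chunked low-pass over the leading (time) axis with carried state.

    The first sample of the first chunk initialises the filter at steady
    state, exactly like :class:`FilterState`.
    """

    def __init__(self, tau: float, dt: float):
        self.alpha = alpha_for(tau, dt)
        self._b = np.array([self.alpha])
        self._a = np.array([1.0, self.alpha - 1.0])
        self._zi: np.ndarray | None = None

    def process(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        shape = x.shape
        flat = x.reshape(shape[0], -1)
        if self._zi is None:
            # zi = (1 - alpha) * y_prev with y_prev = first input
            self._zi = (1.0 - self.alpha) * flat[0][None, :]
        y, self._zi = lfilter(self._b, self._a, flat, axis=0, zi=self._zi)
        return y.reshape(shape)

    @property
    def y_prev(self) -> np.ndarray | None:
        if self._zi is None:
            return None
        if self.alpha >= 1.0:
            return np.zeros_like(self._zi[0])
        return self._zi[0] / (1.0 - self.alpha)


class StreamingHighpass:
    """Chunked complementary high-pass: ``y = x - LP_tau(x)``."""

    def __init__(self, tau: float, dt: float):
        self._lp = StreamingLowpass(tau, dt)

    def process(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x - self._lp.process(x)


class StreamingBandpass:
    """LMC band-pass: LP(tau_L) in series with HP(tau_H)."""

    def __init__(self, tau_l: float, tau_h: float, dt: float):
        self._lp = StreamingLowpass(tau_l, dt)
        self._hp = StreamingHighpass(tau_h, dt)

    def process(self, x: np.ndarray) -> np.ndarray:
        return self._hp.process(self._lp.process(x))
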