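"""Correlation-type elementary motion detectors (EMDs).

Each EMD correlates the signals of two horizontally adjacent receptor lines:
the delayed signal of one line (first-order low-pass, tau_lp = 40 ms)
multiplies the undelayed signal of its neighbour, and the two mirror
half-detector products are half-wave rectified into P+ (preferred direction,
front-to-back, i.e. toward increasing azimuth) and P- (null direction).

Four variants are provided:

``basic``
    The plain correlator described above.
``adaptive``
    A first-order high-pass filter in the undelayed ("cross") arms whose
    time constant tau_h adapts between 0 and 500 ms, driven by the rate of
    change of the delayed arm's low-pass signal; shortens the transient
    oscillations at motion onset while leaving steady-state tuning nearly
    unchanged.
``saturation``
    Contrast saturation in the input lines: signals are scaled by a gain
    calibrated to the 75th percentile of the pre-processed signals and
    passed through tanh before the correlator.
``input_gain``
    Divisive gain control in the input lines: each channel is divided by a
    running estimate of its mean absolute deviation (full-wave rectification
    followed by a low-pass with tau_A = 200 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterState, StreamingLowpass, alpha_for, lowpass_step

__all__ = [
    "AdaptiveParams",
    "SaturationParams",
    "InputGainParams",
    "EmdParams",
    "AdaptiveState",
    "basic_emd_step",
    "update_tau_h",
    "adaptive_emd_step",
    "estimate_saturation_gain",
    "saturate_input",
    "input_gain_control_step",
    "build_emd_field",
    "make_correlator",
    "BasicCorrelator",
    "AdaptiveCorrelator",
    "SaturationCorrelator",
    "InputGainCorrelator",
    "VARIANTS",
]

VARIANTS = ("basic", "adaptive", "saturation", "input_gain")


@dataclass
class AdaptiveParams:
    """Dynamics of the adapting cross-arm high-pass time constant.

    tau_h relaxes toward ``max_tauh`` at rate ``K`` and is driven toward
    ``min_tauh`` at rate ``g * S``, where S is the low-pass-filtered (tau_S)
    magnitude of the delayed arm's signal derivative.  ``g`` maps signal
    scale to rate; its default is ``K / s_half`` so that S = s_half holds
    tau_h at midrange in equilibrium.
    """

    min_tauh: float = 0.0
    max_tauh: float = 0.5
    K: float = 100.0          # 1/s (0.1 kHz)
    tau_S: float = 0.5
    s_half: float = 0.5       # signal-units/s driving tau_h to midrange
    g: float | None = None

    @property
    def gain(self) -> float:
        return self.g if self.g is not None else self.K / self.s_half


@dataclass
class SaturationParams:
    c: float = 1.0            # a_sat = c / mean 75th percentile


@dataclass
class InputGainParams:
    tau_A: float = 0.2
    eps_rel: float = 1e-6     # divisive guard, relative to calibration scale


@dataclass
class EmdParams:
    tau_lp: float = 0.040
    variant: str = "basic"
    adaptive: AdaptiveParams = field(default_factory=AdaptiveParams)
    saturation: SaturationParams = field(default_factory=SaturationParams)
    input_gain: InputGainParams = field(default_factory=InputGainParams)

    def __post_init__(self) -> None:
        if self.tau_lp <= 0:
            raise ValueError("tau_lp must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")


# ---------------------------------------------------------------------------
# per-step scalar/array operations
# ---------------------------------------------------------------------------

def basic_emd_step(left, right, delay_states: tuple[FilterState, FilterState], dt: float):
    """One correlator step for a horizontally adjacent receptor pair.

    ``delay_states`` hold the tau_lp low-pass of the left and right lines.
    Returns the rectified half-detector outputs (P+, P-); P+ reports motion
    from the left receptor toward the right one.
    """
    d_left = lowpass_step(delay_states[0], left, dt)
    d_right = lowpass_step(delay_states[1], right, dt)
    p_plus = np.maximum(0.0, d_left * np.asarray(right, dtype=float))
    p_minus = np.maximum(0.0, np.asarray(left, dtype=float) * d_right)
    return p_plus, p_minus


@dataclass
class AdaptiveState:
    """Per-arm adaptation state: current tau_h and the drive low-pass S."""

    tau_h: float | np.ndarray
    s_state: FilterState
    params: AdaptiveParams = field(default_factory=AdaptiveParams)


def update_tau_h(state: AdaptiveState, L_prime, dt: float):
    """Advance the adapting high-pass time constant by one step.

    S = LP_tauS(|L'|); tau_h follows
    d tau_h/dt = K (max_tauh - tau_h) - g S (tau_h - min_tauh),
    integrated exactly over dt (the ODE is linear in tau_h for fixed S) and
    clamped to [min_tauh, max_tauh].
    """
    p = state.params
    S = lowpass_step(state.s_state, np.abs(L_prime), dt)
    B = p.K + p.gain * S
    A = p.K * p.max_tauh + p.gain * S * p.min_tauh
    eq = A / B
    state.tau_h = np.clip(eq + (state.tau_h - eq) * np.exp(-B * dt), p.min_tauh, p.max_tauh)
    return state.tau_h


def _hp_adaptive_step(lp_state_prev, x, tau_h, dt: float):
    """High-pass step with an elementwise time-varying time constant."""
    tau_h = np.asarray(tau_h, dtype=float)
    a = np.where(tau_h > 1e-12, 1.0 - np.exp(-dt / np.maximum(tau_h, 1e-12)), 1.0)
    lp = lp_state_prev + a * (x - lp_state_prev)
    return x - lp, lp


def adaptive_emd_step(
    left,
    right,
    delay_states: tuple[FilterState, FilterState],
    adaptive_states: tuple[AdaptiveState, AdaptiveState],
    hp_lp_states: list,
    dt: float,
):
    """One adaptive-correlator step for a receptor pair.

    The cross (undelayed) arm is high-pass filtered with tau_h adapted by
    the contralateral delayed low-pass signal's rate of change; the
    previous low-pass outputs are needed to form that derivative.
    """
    d_left_prev = delay_states[0].y_prev
    d_right_prev = delay_states[1].y_prev
    d_left = lowpass_step(delay_states[0], left, dt)
    d_right = lowpass_step(delay_states[1], right, dt)
    dl_dt = 0.0 if d_left_prev is None else (d_left - d_left_prev) / dt
    dr_dt = 0.0 if d_right_prev is None else (d_right - d_right_prev) / dt

    tau_p = update_tau_h(adaptive_states[0], dl_dt, dt)   # HP on right line
    tau_m = update_tau_h(adaptive_states[1], dr_dt, dt)   # HP on left line
    if hp_lp_states[0] is None:
        hp_lp_states[0] = float(right)
        hp_lp_states[1] = float(left)
    h_right, hp_lp_states[0] = _hp_adaptive_step(hp_lp_states[0], float(right), tau_p, dt)
    h_left, hp_lp_states[1] = _hp_adaptive_step(hp_lp_states[1], float(left), tau_m, dt)

    p_plus = np.maximum(0.0, d_left * h_right)
    p_minus = np.maximum(0.0, h_left * d_right)
    return p_plus, p_minus


def estimate_saturation_gain(samples: np.ndarray, c: float = 1.0) -> float:
    """Saturation gain from a calibration window of pre-processed signals.

    ``samples`` has shape (T, ...) with one channel per trailing position.
    The gain is ``c`` divided by the mean over channels of each channel's
    75th percentile of signal magnitude, so the typical strong signal maps
    to tanh(c).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty calibration window")
    q75 = np.percentile(np.abs(samples), 75, axis=0)
    qbar = float(np.mean(q75))
    if qbar <= 0:
        raise ValueError("calibration signals are all zero")
    return c / qbar


def saturate_input(s, a_sat: float):
    """Compressive input nonlinearity: tanh(a_sat * s)."""
    return np.tanh(a_sat * np.asarray(s, dtype=float))


def input_gain_control_step(x, mad_state: FilterState, tau_A: float, dt: float, eps: float = 1e-6):
    """Divisive normalisation by the running mean absolute deviation.

    mad = LP_tauA(|x|); returns x / (mad + eps).
    """
    if tau_A <= 0:
        raise ValueError("tau_A must be positive")
    mad_state.tau = tau_A
    mad = lowpass_step(mad_state, np.abs(x), dt)
    return np.asarray(x, dtype=float) / (mad + eps)


# ---------------------------------------------------------------------------
# streaming correlators over receptor fields
# ---------------------------------------------------------------------------

def _pairing(n_cols: int, periodic: bool):
    if n_cols < 2:
        raise ValueError("need at least 2 receptor columns to build EMDs")
    if periodic:
        left = np.arange(n_cols)
        right = (left + 1) % n_cols
    else:
        left = np.arange(n_cols - 1)
        right = left + 1
    return left, right


def _left_lines(x: np.ndarray, periodic: bool) -> np.ndarray:
    """Signal of the left receptor of each EMD pair (view, no copy)."""
    return x if periodic else x[..., :-1]


def _right_lines(x: np.ndarray, periodic: bool) -> np.ndarray:
    """Signal of the right receptor of each EMD pair."""
    return np.roll(x, -1, axis=-1) if periodic else x[..., 1:]


class BasicCorrelator:
    """Vectorised basic correlator over a (time, rows, cols) stream."""

    needs_calibration = False

    def __init__(self, n_cols: int, params: EmdParams, dt: float, periodic: bool = False):
        self.params = params
        self.dt = dt
        self.periodic = periodic
        self.left, self.right = _pairing(n_cols, periodic)
        self._delay = StreamingLowpass(params.tau_lp, dt)

    @property
    def n_emd(self) -> int:
        return len(self.left)

    def _input_lines(self, L: np.ndarray) -> np.ndarray:
        return L

    def process(self, L: np.ndarray):
        """Map a pre-processed chunk (T, rows, cols) to (P+, P-)."""
        s = self._input_lines(np.asarray(L, dtype=float))
        d = self._delay.process(s)
        p_plus = np.maximum(0.0, _left_lines(d, self.periodic) * _right_lines(s, self.periodic))
        p_minus = np.maximum(0.0, _left_lines(s, self.periodic) * _right_lines(d, self.periodic))
        return p_plus, p_minus


class SaturationCorrelator(BasicCorrelator):
    """Basic correlator with tanh contrast saturation in the input lines."""

    needs_calibration = True

    def __init__(self, n_cols: int, params: EmdParams, dt: float, periodic: bool = False):
        super().__init__(n_cols, params, dt, periodic)
        self.a_sat: float | None = None

    def calibrate(self, samples: np.ndarray) -> None:
        self.a_sat = estimate_saturation_gain(samples, self.params.saturation.c)

    def _input_lines(self, L: np.ndarray) -> np.ndarray:
        if self.a_sat is None:
            raise RuntimeError("saturation correlator must be calibrated first")
        return saturate_input(L, self.a_sat)


class InputGainCorrelator(BasicCorrelator):
    """Basic correlator with divisive gain control in the input lines."""

    needs_calibration = True

    def __init__(self, n_cols: int, params: EmdParams, dt: float, periodic: bool = False):
        super().__init__(n_cols, params, dt, periodic)
        self._mad = StreamingLowpass(params.input_gain.tau_A, dt)
        self.eps: float | None = None

    def calibrate(self, samples: np.ndarray) -> None:
        q75 = np.percentile(np.abs(np.asarray(samples, dtype=float)), 75, axis=0)
        scale = float(np.mean(q75))
        if scale <= 0:
            raise ValueError("calibration signals are all zero")
        self.eps = self.params.input_gain.eps_rel * scale

    def _input_lines(self, L: np.ndarray) -> np.ndarray:
        if self.eps is None:
            raise RuntimeError("input-gain correlator must be calibrated first")
        mad = self._mad.process(np.abs(L))
        return L / (mad + self.eps)


class AdaptiveCorrelator:
    """Correlator with adapting high-pass filters in the cross arms.

    The delayed low-pass and the S drive are linear time-invariant and run
    vectorised; only the tau_h update and the time-varying high-pass need a
    per-step loop within each chunk.
    """

    needs_calibration = False

    def __init__(self, n_cols: int, params: EmdParams, dt: float, periodic: bool = False):
        self.params = params
        self.dt = dt
        self.periodic = periodic
        self.left, self.right = _pairing(n_cols, periodic)
        self._delay = StreamingLowpass(params.tau_lp, dt)
        self._s_lp = StreamingLowpass(params.adaptive.tau_S, dt)
        self._d_prev: np.ndarray | None = None
        self._tau_p = None      # tau_h of the HP on the right (P+) line
        self._tau_m = None
        self._hp_lp_p = None    # internal LP state of the adaptive HPs
        self._hp_lp_m = None

    @property
    def n_emd(self) -> int:
        return len(self.left)

    def process(self, L: np.ndarray):
        L = np.asarray(L, dtype=float)
        d = self._delay.process(L)
        prev = self._d_prev if self._d_prev is not None else d[0]
        d_shift = np.concatenate([prev[None], d[:-1]], axis=0)
        ldot = (d - d_shift) / self.dt
        self._d_prev = d[-1].copy()
        S = self._s_lp.process(np.abs(ldot))

        p = self.params.adaptive
        if self._tau_p is None:
            shape = L.shape[1:-1] + (self.n_emd,)
            self._tau_p = np.full(shape, p.max_tauh)
            self._tau_m = np.full(shape, p.max_tauh)
            self._hp_lp_p = _right_lines(L[0], self.periodic).copy()
            self._hp_lp_m = _left_lines(L[0], self.periodic).copy()

        g = p.gain
        T = L.shape[0]
        d_left = _left_lines(d, self.periodic)
        d_right = _right_lines(d, self.periodic)
        S_left = _left_lines(S, self.periodic)
        S_right = _right_lines(S, self.periodic)
        u_left = _left_lines(L, self.periodic)
        u_right = _right_lines(L, self.periodic)
        p_plus = np.empty(L.shape[:-1] + (self.n_emd,))
        p_minus = np.empty_like(p_plus)
        for t in range(T):
            for tau, drive in ((self._tau_p, S_left[t]), (self._tau_m, S_right[t])):
                B = p.K + g * drive
                eq = (p.K * p.max_tauh + g * drive * p.min_tauh) / B
                np.clip(eq + (tau - eq) * np.exp(-B * self.dt), p.min_tauh, p.max_tauh, out=tau)
            a_p = np.where(self._tau_p > 1e-12, 1.0 - np.exp(-self.dt / np.maximum(self._tau_p, 1e-12)), 1.0)
            a_m = np.where(self._tau_m > 1e-12, 1.0 - np.exp(-self.dt / np.maximum(self._tau_m, 1e-12)), 1.0)
            self._hp_lp_p += a_p * (u_right[t] - self._hp_lp_p)
            self._hp_lp_m += a_m * (u_left[t] - self._hp_lp_m)
            h_r = u_right[t] - self._hp_lp_p
            h_l = u_left[t] - self._hp_lp_m
            np.maximum(0.0, d_left[t] * h_r, out=p_plus[t])
            np.maximum(0.0, h_l * d_right[t], out=p_minus[t])
        return p_plus, p_minus


_CORRELATORS = {
    "basic": BasicCorrelator,
    "adaptive": AdaptiveCorrelator,
    "saturation": SaturationCorrelator,
    "input_gain": InputGainCorrelator,
}


def make_correlator(variant: str, n_cols: int, params: EmdParams, dt: float, periodic: bool = False):
    if variant not in _CORRELATORS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    return _CORRELATORS[variant](n_cols, params, dt, periodic)


def build_emd_field(
    receptor_field: np.ndarray,
    params: EmdParams,
    dt: float,
    periodic: bool = False,
    calibration: np.ndarray | None = None,
):
    """Apply the selected correlator variant over a full receptor stream.

    ``receptor_field`` has shape (T, rows, cols); the output half-detector
    fields have n_emd = cols - 1 columns for an open sub-array and
    n_emd = cols with wraparound for the full periodic ring.  Variants that
    need calibration use ``calibration`` if given, else the input stream
    itself.
    """
    receptor_field = np.asarray(receptor_field, dtype=float)
    if receptor_field.ndim != 3:
        raise ValueError("receptor_field must have shape (T, rows, cols)")
    if receptor_field.shape[-1] < 2:
        raise ValueError("need at least 2 receptor columns")
    corr = make_correlator(params.variant, receptor_field.shape[-1], params, dt, periodic)
    if corr.needs_calibration:
        cal = calibration if calibration is not None else receptor_field
        corr.calibrate(cal.reshape(cal.shape[0], -1))
    return corr.process(receptor_field)
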