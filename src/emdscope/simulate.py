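"""Stimulus-response simulation engine.

Drives the full loop — panorama rotation, peripheral front end, correlator
stage, gain-control pooling — at the 1 kHz sample rate.  The default
stimulus rotates the scene at 60 deg/s in the preferred (front-to-back)
direction for 12 s; the first 6 s (one full rotation) are discarded so only
the non-transient response is analysed.

All receptive fields passed to :func:`run_simulation` share one front-end
and one EMD pass; the half-detector fields are reduced into per-field
conductance sums chunk by chunk, so memory stays proportional to grid size
times the number of fields rather than to the trace length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import modulation_sd, normalize_response
from .emd import EmdParams, make_correlator
from .lptc import GainControlParams, ReceptiveField, gain_control_integrate, make_rect_rf
from .optics import FrontEnd, OpticsParams, ReceptorGrid, estimate_I0, gaussian_prefilter
from .panorama import Panorama

__all__ = ["StimulusSpec", "ResponseTrace", "run_simulation", "sweep_1d", "sweep_2d"]


@dataclass
class StimulusSpec:
    """Constant-velocity horizontal rotation of the panorama.

    Positive velocity moves image features in the preferred direction of
    the detectors (front-to-back, toward increasing receptor azimuth).
    """

    velocity: float = 60.0     # deg/s
    duration: float = 12.0     # s
    dt: float = 0.001          # s
    discard: float = 6.0       # s of initial transient removed from traces

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.discard >= 0:
            raise ValueError("need duration > discard >= 0")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def n_discard(self) -> int:
        return round(self.discard / self.dt)

    @property
    def n_rotations(self) -> float:
        return self.velocity * self.duration / 360.0


@dataclass
class ResponseTrace:
    """Retained LPTC output and the provenance of the run."""

    z: np.ndarray
    dt: float
    discard: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)


def _offsets(stim: StimulusSpec, start: int, stop: int) -> np.ndarray:
    # a feature at panorama azimuth A is seen at receptor azimuth A + v*t,
    # i.e. it drifts toward increasing azimuth (preferred direction) for v > 0
    t = np.arange(start, stop) * stim.dt
    return -stim.velocity * t


def _calibrate(
    correlator,
    p: Panorama,
    grid: ReceptorGrid,
    optics: OpticsParams,
    stim: StimulusSpec,
    chunk: int,
    stride: int = 10,
) -> None:
    """Collect pre-processed signals over the calibration window.

    The window is the discarded initial segment (or one full rotation if
    nothing is discarded); per-channel quartiles are estimated from every
    ``stride``-th sample to bound memory.
    """
    if stim.n_discard > 0:
        n_cal = stim.n_discard
    elif stim.velocity != 0:
        n_cal = min(stim.n_steps, round(360.0 / abs(stim.velocity) / stim.dt))
    else:
        n_cal = stim.n_steps
    fe = FrontEnd(p, grid, optics, prefiltered=True)
    kept = []
    for start in range(0, n_cal, chunk):
        stop = min(start + chunk, n_cal)
        L = fe.run(_offsets(stim, start, stop))
        kept.append(L[(-start) % stride :: stride])
    samples = np.concatenate(kept, axis=0)
    correlator.calibrate(samples.reshape(samples.shape[0], -1))


def run_simulation(
    p: Panorama,
    variant: str,
    rf_list: Sequence[ReceptiveField],
    stim: StimulusSpec | None = None,
    grid: ReceptorGrid | None = None,
    optics: OpticsParams | None = None,
    emd: EmdParams | None = None,
    gc: GainControlParams | None = None,
    chunk: int = 256,
    keep_transient: bool = False,
) -> list[ResponseTrace]:
    """Simulate one panorama under one EMD variant for many receptive fields.

    Returns one :class:`ResponseTrace` per receptive field, transient
    removed (unless ``keep_transient``).  The computation is fully
    deterministic: identical inputs give bit-identical traces.
    """
    stim = stim or StimulusSpec()
    grid = grid or ReceptorGrid.full()
    optics = optics or OpticsParams()
    # working point from the unblurred scene; dt follows the stimulus clock
    optics = replace(
        optics,
        dt=stim.dt,
        I0=optics.I0 if optics.I0 is not None else estimate_I0(p),
    )
    emd = emd or EmdParams()
    emd.variant = variant
    if not p.periodic_azimuth and abs(stim.velocity) * stim.duration > 360.0:
        raise ValueError("non-periodic panorama cannot be rotated beyond one traversal")

    pf = gaussian_prefilter(p, optics.delta_rho)
    correlator = make_correlator(variant, grid.n_az, emd, stim.dt, periodic=grid.periodic)
    if correlator.needs_calibration:
        _calibrate(correlator, pf, grid, optics, stim, chunk)

    fe = FrontEnd(pf, grid, optics, prefiltered=True)
    n_emd = correlator.n_emd
    for rf in rf_list:
        if rf.row_indices.max() >= grid.n_elev or rf.col_indices.max() >= n_emd:
            raise ValueError("receptive field exceeds the EMD field bounds")

    n = stim.n_steps
    traces = [np.empty(n) for _ in rf_list]
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        L = fe.run(_offsets(stim, start, stop))
        p_plus, p_minus = correlator.process(L)
        for trace, rf in zip(traces, rf_list):
            trace[start:stop] = gain_control_integrate(p_plus, p_minus, rf, gc)

    cut = 0 if keep_transient else stim.n_discard
    meta_base = {
        "variant": variant,
        "velocity": stim.velocity,
        "duration": stim.duration,
        "dt": stim.dt,
        "discard": stim.discard,
        "grid": {"phi": grid.phi, "n_az": grid.n_az, "n_elev": grid.n_elev},
    }
    return [
        ResponseTrace(
            trace[cut:],
            dt=stim.dt,
            discard=stim.discard,
            meta={**meta_base, "rf": rf.descriptor},
        )
        for trace, rf in zip(traces, rf_list)
    ]


def _full_field_rf(grid: ReceptorGrid) -> ReceptiveField:
    return make_rect_rf(grid.n_elev, grid.n_az, grid)


def sweep_1d(
    p: Panorama,
    variant: str,
    elevations: Sequence[float],
    n_list: Sequence[int],
    stim: StimulusSpec | None = None,
    grid: ReceptorGrid | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Modulation SD of one-row EMD arrays vs elevation and horizontal size.

    One front-end/EMD pass per call; every array's normalised response is
    referenced against the full-field response of the same grid.  Returns a
    DataFrame indexed by elevation with one column per receptor count n.
    """
    grid = grid or ReceptorGrid.full()
    n_list = sorted(n_list)
    rfs = [
        make_rect_rf(1, n, grid, centre=(180.0, el))
        for el in elevations
        for n in n_list
    ]
    rfs.append(_full_field_rf(grid))
    traces = run_simulation(p, variant, rfs, stim=stim, grid=grid, **kwargs)
    n_full = normalize_response(traces[-1])
    s = np.array(
        [modulation_sd(normalize_response(tr), n_full) for tr in traces[:-1]]
    ).reshape(len(elevations), len(n_list))
    return pd.DataFrame(s, index=pd.Index(elevations, name="elevation"),
                        columns=pd.Index(n_list, name="n"))


def sweep_2d(
    p: Panorama,
    variant: str,
    m_list: Sequence[int],
    n_list: Sequence[int],
    stim: StimulusSpec | None = None,
    grid: ReceptorGrid | None = None,
    centre: tuple[float, float] = (180.0, 0.0),
    **kwargs,
) -> pd.DataFrame:
    """Modulation SD of rectangular m x n receptor arrays centred on the horizon."""
    grid = grid or ReceptorGrid.full()
    m_list, n_list = sorted(m_list), sorted(n_list)
    rfs = [make_rect_rf(m, n, grid, centre=centre) for m in m_list for n in n_list]
    rfs.append(_full_field_rf(grid))
    traces = run_simulation(p, variant, rfs, stim=stim, grid=grid, **kwargs)
    n_full = normalize_response(traces[-1])
    s = np.array(
        [modulation_sd(normalize_response(tr), n_full) for tr in traces[:-1]]
    ).reshape(len(m_list), len(n_list))
    return pd.DataFrame(s, index=pd.Index(m_list, name="m"),
                        columns=pd.Index(n_list, name="n"))
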