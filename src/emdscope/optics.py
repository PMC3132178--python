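"""Peripheral optics and early visual processing (input stage).

The stage mirrors the fly eye periphery: a Gaussian spatial low-pass with
full width at half maximum equal to the ommatidial acceptance angle
(delta_rho = 1.64 deg), sampling on a rectangular receptor grid with
inter-receptor angle phi = 1.25 deg, a static Naka-Rushton transduction
working at the scene's geometric-mean luminance, and the band-pass temporal
filtering of the lamina monopolar cells (LMCs, LP tau_L = 8 ms followed by
HP tau_H = 400 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filters import StreamingBandpass
from .panorama import Panorama

__all__ = [
    "FWHM_TO_SIGMA",
    "OpticsParams",
    "ReceptorGrid",
    "gaussian_prefilter",
    "sample_receptors",
    "naka_rushton",
    "estimate_I0",
    "FrontEnd",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class OpticsParams:
    """Front-end constants (angles in degrees, times in seconds)."""

    delta_rho: float = 1.64      # ommatidial acceptance angle (FWHM)
    a_nr: float = 0.7            # Naka-Rushton exponent
    I0: float | None = None      # mid-response intensity; None -> geometric mean
    tau_L: float = 0.008         # LMC low-pass time constant
    tau_H: float = 0.400         # LMC high-pass time constant
    dt: float = 0.001            # simulation step

    def __post_init__(self) -> None:
        if self.tau_L <= 0 or self.tau_H <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be positive")


@dataclass
class ReceptorGrid:
    """Rectangular photoreceptor grid.

    ``azimuths``/``elevations`` hold the viewing directions of the columns
    and rows.  For a periodic grid the azimuths close the full ring:
    n_az * phi = 360.
    """

    phi: float
    azimuths: np.ndarray
    elevations: np.ndarray
    periodic: bool

    def __post_init__(self) -> None:
        self.azimuths = np.asarray(self.azimuths, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.periodic and abs(len(self.azimuths) * self.phi - 360.0) > 1e-6:
            raise ValueError("periodic grid requires n_az * phi = 360")
        if len(self.elevations) > 1 and not np.all(np.diff(self.elevations) < 0):
            raise ValueError("rows must be ordered top (max elevation) to bottom")

    @property
    def n_az(self) -> int:
        return len(self.azimuths)

    @property
    def n_elev(self) -> int:
        return len(self.elevations)

    @classmethod
    def full(cls, phi: float = 1.25, n_elev: int = 56) -> "ReceptorGrid":
        """Full periodic ring, rows centred symmetrically about the horizon."""
        n_az = round(360.0 / phi)
        if abs(n_az * phi - 360.0) > 1e-9:
            raise ValueError("phi must divide 360 degrees")
        elevations = ((n_elev - 1) / 2.0 - np.arange(n_elev)) * phi
        return cls(phi, np.arange(n_az) * phi, elevations, periodic=True)

    @classmethod
    def horizon(cls, phi: float = 1.25) -> "ReceptorGrid":
        """Single receptor row on the horizon, full periodic ring."""
        n_az = round(360.0 / phi)
        return cls(phi, np.arange(n_az) * phi, np.array([0.0]), periodic=True)


def gaussian_prefilter(p: Panorama, delta_rho: float = 1.64) -> Panorama:
    """Blur a panorama with the ommatidial Gaussian (FWHM = delta_rho).

    Azimuth is convolved circularly (the panorama wraps); elevation uses
    edge replication.  The per-row mean is conserved exactly by the
    circular pass.
    """
    if p.deg_per_pixel > delta_rho / 4.0 + 1e-12:
        raise ValueError(
            "panorama resolution too coarse for the acceptance angle "
            f"(need <= {delta_rho / 4.0:.4f} deg/px, got {p.deg_per_pixel})"
        )
    sigma_px = delta_rho * FWHM_TO_SIGMA / p.deg_per_pixel
    blurred = ndimage.gaussian_filter(
        p.luminance.astype(float), sigma=sigma_px, mode=["nearest", "wrap"], truncate=6.0
    )
    return Panorama(
        blurred,
        deg_per_pixel=p.deg_per_pixel,
        elevation_range=p.elevation_range,
        periodic_azimuth=p.periodic_azimuth,
    )


def _row_coordinates(p: Panorama, elevations: np.ndarray):
    top = p.elevation_range[1]
    r = (top - np.asarray(elevations, dtype=float)) / p.deg_per_pixel
    if np.any(r < -1e-9) or np.any(r > p.n_rows - 1 + 1e-9):
        raise ValueError("receptor elevations exceed the panorama elevation range")
    r = np.clip(r, 0.0, p.n_rows - 1)
    i0 = np.minimum(np.floor(r).astype(int), p.n_rows - 2) if p.n_rows > 1 else np.zeros_like(r, dtype=int)
    w = r - i0
    return i0, w


def sample_receptors(
    p_filtered: Panorama, grid: ReceptorGrid, azimuth_offset_deg: float
) -> np.ndarray:
    """Luminance seen by each receptor at the given azimuthal image offset.

    Receptor (row, col) samples the panorama at (row elevation,
    receptor azimuth + offset) by bilinear interpolation; azimuth wraps
    modulo 360 degrees.
    """
    p = p_filtered
    i0, wr = _row_coordinates(p, grid.elevations)
    x = ((grid.azimuths + azimuth_offset_deg) / p.deg_per_pixel) % p.n_cols
    j0 = np.floor(x).astype(int)
    wc = x - j0
    j1 = (j0 + 1) % p.n_cols
    lum = p.luminance
    if p.n_rows == 1:
        row = lum[0]
        return (1 - wc) * row[j0] + wc * row[j1]
    top = (1 - wc)[None, :] * lum[np.ix_(i0, j0)] + wc[None, :] * lum[np.ix_(i0, j1)]
    bot = (1 - wc)[None, :] * lum[np.ix_(i0 + 1, j0)] + wc[None, :] * lum[np.ix_(i0 + 1, j1)]
    return (1 - wr)[:, None] * top + wr[:, None] * bot


def naka_rushton(I, I0: float, a_nr: float = 0.7):
    """Saturating transduction ``u = I**a / (I**a + I0**a)``, in [0, 1).

    ``I0`` is the mid-response intensity (u = 0.5 at I = I0); ``a_nr``
    sets the slope of the transfer function.
    """
    I = np.asarray(I, dtype=float)
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    if np.any(I < 0):
        raise ValueError("luminance must be non-negative")
    Ia = I ** a_nr
    return Ia / (Ia + I0 ** a_nr)


def estimate_I0(p: Panorama) -> float:
    """Geometric mean of the scene luminance (zero-guarded).

    Sets the working point of the Naka-Rushton transduction per image, a
    static stand-in for the luminance history the photoreceptors adapt to.
    """
    lum = p.luminance
    mean = lum.mean()
    if mean <= 0:
        raise ValueError("cannot estimate I0 of an all-zero image")
    eps = 1e-6 * mean
    return float(np.exp(np.mean(np.log(np.maximum(lum, eps)))))


class FrontEnd:
    """Streaming input stage: sample -> Naka-Rushton -> LMC band-pass.

    The Gaussian prefilter and the elevation interpolation are motion
    independent, so both are applied once at construction; per time step
    only the azimuthal interpolation and the temporal filters run.
    ``run(offsets)`` consumes a chunk of azimuthal offsets (degrees, one per
    time step) and returns the pre-processed receptor field of shape
    ``(len(offsets), n_elev, n_az)``.
    """

    def __init__(
        self,
        p: Panorama,
        grid: ReceptorGrid,
        params: OpticsParams | None = None,
        prefiltered: bool = False,
    ):
        self.params = params or OpticsParams()
        self.grid = grid
        pf = p if prefiltered else gaussian_prefilter(p, self.params.delta_rho)
        self.I0 = self.params.I0 if self.params.I0 is not None else estimate_I0(p)
        # collapse the (fixed) elevation interpolation into one row per
        # receptor row: afterwards sampling is purely azimuthal
        i0, wr = _row_coordinates(pf, grid.elevations)
        lum = pf.luminance
        if pf.n_rows == 1:
            rows = np.tile(lum[0], (grid.n_elev, 1))
        else:
            rows = (1 - wr)[:, None] * lum[i0] + wr[:, None] * lum[i0 + 1]
        self._rows = rows              # (n_elev, W)
        self._rows_t = np.ascontiguousarray(rows.T)
        self._w = pf.n_cols
        self._dpp = pf.deg_per_pixel
        self._bandpass = StreamingBandpass(self.params.tau_L, self.params.tau_H, self.params.dt)

    def sample(self, offsets_deg: np.ndarray) -> np.ndarray:
        """Bilinear azimuthal sampling for a chunk of offsets."""
        offsets_deg = np.atleast_1d(np.asarray(offsets_deg, dtype=float))
        x = ((self.grid.azimuths[None, :] + offsets_deg[:, None]) / self._dpp) % self._w
        j0 = np.floor(x).astype(int)
        wc = x - j0
        j1 = (j0 + 1) % self._w
        # gather on the transposed field keeps the output cache-friendly
        rows_t = self._rows_t  # (W, n_elev)
        out = (1 - wc)[..., None] * rows_t[j0] + wc[..., None] * rows_t[j1]
        return np.ascontiguousarray(np.swapaxes(out, 1, 2))  # (T, n_elev, n_az)

    def run(self, offsets_deg: np.ndarray) -> np.ndarray:
        lum = self.sample(offsets_deg)
        u = naka_rushton(lum, self.I0, self.params.a_nr)
        return self._bandpass.process(u)
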