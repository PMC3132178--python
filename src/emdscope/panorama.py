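"""Panoramic luminance images: container, synthesis, and file I/O.

A :class:`Panorama` is a horizontally periodic luminance field covering the
full 360 degrees of azimuth and roughly +/-35 degrees of elevation, with the
horizon at the vertical centre.  Natural scenes of this kind share a
broadband, roughly 1/f spatial amplitude spectrum, but sky and ground differ
strongly in local contrast.  :func:`generate_natural_panorama` produces
surrogate scenes with exactly these statistics from filtered Gaussian noise;
:func:`generate_sine_panorama` and :func:`generate_step_panorama` provide
deterministic fixtures with closed-form properties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Panorama",
    "SynthesisSpec",
    "generate_natural_panorama",
    "generate_sine_panorama",
    "generate_step_panorama",
    "read_panorama",
    "write_panorama",
    "radial_amplitude_slope",
]


@dataclass
class Panorama:
    """A horizontally periodic 2D luminance field with angular metadata.

    Parameters
    ----------
    luminance
        2D array, rows = elevation (top row = highest elevation), columns =
        azimuth.  Linear luminance in arbitrary units; all values must be
        finite and non-negative.
    deg_per_pixel
        Angular resolution, identical along both axes.  Column ``j`` views
        azimuth ``j * deg_per_pixel``; rows are spaced by the same amount.
    elevation_range
        ``(min_deg, max_deg)`` of the row centres, 0 deg at the horizon.
    periodic_azimuth
        True for full panoramas: the azimuthal extent then spans exactly
        360 degrees and column 0 neighbours column W-1.
    """

    luminance: np.ndarray
    deg_per_pixel: float
    elevation_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    periodic_azimuth: bool = True

    def __post_init__(self) -> None:
        self.luminance = np.asarray(self.luminance)
        if self.luminance.ndim != 2:
            raise ValueError("luminance must be a 2D array")
        if not np.all(np.isfinite(self.luminance)):
            raise ValueError("luminance must be finite")
        if np.any(self.luminance < 0):
            raise ValueError("luminance must be non-negative")
        h, w = self.luminance.shape
        if self.elevation_range is None:
            half = (h - 1) * self.deg_per_pixel / 2.0
            self.elevation_range = (-half, half)
        self.elevation_range = (float(self.elevation_range[0]), float(self.elevation_range[1]))
        span = self.elevation_range[1] - self.elevation_range[0]
        if abs(span - (h - 1) * self.deg_per_pixel) > 1e-6:
            raise ValueError(
                "elevation_range span must equal (n_rows - 1) * deg_per_pixel"
            )
        if self.periodic_azimuth and abs(w * self.deg_per_pixel - 360.0) > 1e-6:
            raise ValueError("periodic panorama must span exactly 360 degrees")

    @property
    def n_rows(self) -> int:
        return self.luminance.shape[0]

    @property
    def n_cols(self) -> int:
        return self.luminance.shape[1]

    @property
    def row_elevations(self) -> np.ndarray:
        """Elevation of each row centre, descending from the top row."""
        top = self.elevation_range[1]
        return top - np.arange(self.n_rows) * self.deg_per_pixel

    @property
    def col_azimuths(self) -> np.ndarray:
        return np.arange(self.n_cols) * self.deg_per_pixel


@dataclass
class SynthesisSpec:
    """Parameters of the natural-statistics surrogate panorama.

    ``spectral_slope`` is the exponent beta of the 1/f**beta amplitude
    spectrum (natural scenes: beta ~ 1).  ``sky_ground_contrast_ratio`` is
    the ratio of RMS contrast of the lower ("ground") to the upper ("sky")
    half.  ``target_rms_contrast`` is the global RMS contrast (std of
    luminance over its mean) the generated image must hit.
    """

    width_px: int = 2880
    height_px: int = 560
    spectral_slope: float = 1.0
    sky_ground_contrast_ratio: float = 3.0
    target_rms_contrast: float = 0.4
    mean_luminance: float = 1000.0
    seed: int = 0
    n_az_receptors: int = 288

    def validate(self) -> None:
        if self.width_px % 2 != 0:
            raise ValueError("width_px must be even")
        if self.width_px % self.n_az_receptors != 0:
            raise ValueError(
                f"width_px must be divisible by the azimuthal receptor count "
                f"({self.n_az_receptors})"
            )
        if self.height_px < 2 or self.height_px % 2 != 0:
            raise ValueError("height_px must be even and >= 2")
        if self.target_rms_contrast <= 0:
            raise ValueError("target_rms_contrast must be positive")
        if self.mean_luminance <= 0:
            raise ValueError("mean_luminance must be positive")
        if self.sky_ground_contrast_ratio <= 0:
            raise ValueError("sky_ground_contrast_ratio must be positive")


def _spectral_noise(rng: np.random.Generator, height: int, width: int, beta: float) -> np.ndarray:
    """Real Gaussian noise field with a 1/f**beta amplitude spectrum.

    Synthesis in the 2D Fourier domain makes the field exactly periodic in
    both axes, which guarantees a seamless azimuthal wraparound.
    """
    white = rng.standard_normal((height, width))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-beta)
    g = np.fft.ifft2(spec * amp).real
    return g


def generate_natural_panorama(spec: SynthesisSpec) -> Panorama:
    """Generate a surrogate natural panorama from shaped Gaussian noise.

    The upper half emulates a low-contrast sky, the lower half a
    high-contrast ground; both share the same mean luminance.  After
    clipping negative luminance at zero the field is rescaled to the
    requested mean, and the fluctuation amplitude is iterated until the
    global RMS contrast is within 0.5 % of ``target_rms_contrast``.
    Identical seeds yield bit-identical images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = _spectral_noise(rng, spec.height_px, spec.width_px, spec.spectral_slope)

    half = spec.height_px // 2
    sky = g[:half]
    ground = g[half:]
    sky = (sky - sky.mean()) / sky.std()
    ground = (ground - ground.mean()) / ground.std()
    r = spec.sky_ground_contrast_ratio
    # unit global RMS with per-half RMS ratio r (equal-sized halves)
    norm = np.sqrt((1.0 + r * r) / 2.0)
    pattern = np.concatenate([sky / norm, ground * (r / norm)], axis=0)

    target = spec.target_rms_contrast
    scale = target
    lum = None
    for _ in range(16):
        lum = spec.mean_luminance * (1.0 + scale * pattern)
        np.clip(lum, 0.0, None, out=lum)
        lum *= spec.mean_luminance / lum.mean()
        achieved = lum.std() / lum.mean()
        if abs(achieved - target) <= 5e-3 * target:
            break
        scale *= target / achieved
    return Panorama(lum, deg_per_pixel=360.0 / spec.width_px)


def generate_sine_panorama(
    spatial_wavelength_deg: float,
    contrast: float,
    mean_luminance: float,
    size: tuple[int, int] = (560, 2880),
) -> Panorama:
    """Vertical sine grating: ``L(az) = mean * (1 + c * sin(2*pi*az/lambda))``.

    The wavelength must divide 360 degrees so the grating closes on itself.
    """
    n_cycles = 360.0 / spatial_wavelength_deg
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError("360 / spatial_wavelength_deg must be an integer")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must be in [0, 1]")
    if mean_luminance <= 0:
        raise ValueError("mean_luminance must be positive")
    h, w = size
    az = np.arange(w) * (360.0 / w)
    profile = mean_luminance * (1.0 + contrast * np.sin(2 * np.pi * az / spatial_wavelength_deg))
    lum = np.broadcast_to(profile, (h, w)).copy()
    return Panorama(lum, deg_per_pixel=360.0 / w)


def generate_step_panorama(
    edge_azimuth_deg: float,
    low: float,
    high: float,
    size: tuple[int, int] = (560, 2880),
) -> Panorama:
    """Two-level panorama with one rising and one falling luminance edge.

    The high level occupies the half circle starting at ``edge_azimuth_deg``;
    the falling edge sits 180 degrees later, so the field stays periodic.
    """
    if low < 0 or high < 0:
        raise ValueError("luminance levels must be non-negative")
    h, w = size
    az = np.arange(w) * (360.0 / w)
    in_high = ((az - edge_azimuth_deg) % 360.0) < 180.0
    profile = np.where(in_high, float(high), float(low))
    lum = np.broadcast_to(profile, (h, w)).copy()
    return Panorama(lum, deg_per_pixel=360.0 / w)


def write_panorama(p: Panorama, path: str | Path) -> None:
    """Write a panorama as a float grayscale TIFF plus a JSON sidecar.

    The array dtype is preserved, so a read-back is bit-exact.
    """
    path = Path(path)
    tifffile.imwrite(path, p.luminance)
    meta = {
        "deg_per_pixel": p.deg_per_pixel,
        "elevation_range": list(p.elevation_range),
        "periodic_azimuth": p.periodic_azimuth,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_panorama(path: str | Path) -> Panorama:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    lum = tifffile.imread(path)
    return Panorama(
        lum,
        deg_per_pixel=float(meta["deg_per_pixel"]),
        elevation_range=tuple(meta["elevation_range"]),
        periodic_azimuth=bool(meta["periodic_azimuth"]),
    )


def radial_amplitude_slope(
    p: Panorama, f_lo: float = 0.005, f_hi: float = 0.25
) -> float:
    """Log-log slope of the radially averaged 2D amplitude spectrum.

    Frequencies are in cycles/pixel; the fit band excludes DC and the
    neighbourhood of Nyquist.  For a 1/f**beta field the slope is -beta.
    """
    lum = p.luminance - p.luminance.mean()
    amp = np.abs(np.fft.fft2(lum))
    fy = np.fft.fftfreq(p.n_rows)[:, None]
    fx = np.fft.fftfreq(p.n_cols)[None, :]
    f = np.hypot(fy, fx).ravel()
    a = amp.ravel()
    sel = (f >= f_lo) & (f <= f_hi)
    # average amplitude within log-spaced annuli, then fit a line
    edges = np.geomspace(f_lo, f_hi, 25)
    idx = np.digitize(f[sel], edges)
    fs, amps = [], []
    for k in range(1, len(edges)):
        m = idx == k
        if m.sum() > 0:
            fs.append(np.exp(np.mean(np.log(f[sel][m]))))
            amps.append(np.mean(a[sel][m]))
    coef = np.polyfit(np.log(fs), np.log(amps), 1)
    return float(coef[0])
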