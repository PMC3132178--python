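# Methods

## Scope and model overview

`emdscope` simulates the fly motion-vision pathway from the compound-eye
optics to wide-field motion-sensitive neurons (lobula-plate tangential
cells, LPTCs) and quantifies *pattern-dependent response modulations*: the
fluctuation of the response to constant-velocity motion that is caused by
local image structure rather than by velocity changes.  The pipeline has
three stages applied to a horizontally periodic panoramic luminance field:

1. **Input stage.**  The panorama is blurred by a 2D Gaussian with full
   width at half maximum equal to the ommatidial acceptance angle
   Δρ = 1.64°, sampled on a rectangular receptor grid with
   inter-receptor angle Φ = 1.25° (288 receptors close the azimuthal
   ring; 56 rows cover ±34.375° elevation), transduced by a Naka-Rushton
   function u = Iᵃ/(Iᵃ + I₀ᵃ) with a = 0.7 and I₀ the geometric mean of
   the scene luminance, and band-pass filtered like a lamina monopolar
   cell: a recursive first-order low-pass (τ_L = 8 ms) followed by a
   first-order high-pass (τ_H = 400 ms).  Motion is simulated by shifting
   the sampling rasters horizontally at 1 kHz with bilinear interpolation.
2. **Correlator stage.**  Nearest-neighbour elementary motion detectors
   (EMDs): the τ_lp = 40 ms low-pass-delayed signal of one line multiplies
   the undelayed signal of its right neighbour; both mirror-symmetric
   half-detector products are half-wave rectified into P⁺ (preferred,
   front-to-back) and P⁻.  Four variants: *basic*; *adaptive* (high-pass
   with adapting time constant τ_h ∈ [0, 500] ms in the undelayed arms);
   *contrast saturation* (tanh compression of the input lines, gain set so
   the typical strong signal maps to tanh(1)); *input gain control*
   (divisive normalisation of each line by the low-pass-filtered,
   τ_A = 200 ms, magnitude of its own signal).
3. **Integration stage.**  Gain-control pooling over a receptive field
   with weights w: Z = (S⁺ − S⁻)/(1 + S⁺ + S⁻) with S± = Σ w·P±.  The
   sums act as conductances, so |Z| < 1 and the response grows sublinearly
   with receptive-field size.

The analysis normalises each retained trace to its time mean,
N_t = Z_t/Z̄ − 1, and measures the modulation of a given geometry as the
RMS deviation from the normalised full-field trace,
s = √(mean_t (N_t^{m,n} − N_t^{full})²); s ≡ 0 for the full field.
Population (1/T) normalisation is used everywhere for bit-reproducibility.

## Temporal discretisation

All first-order filters use the exact exponential update
y_t = y_{t−1} + α(x_t − y_{t−1}) with α = 1 − exp(−dt/τ), which is
unconditionally stable and closed-form testable.  The high-pass is
identity-minus-low-pass, so LP and HP are exactly complementary at every
step.  Filter states initialise to the first sample's steady state, which
removes the artificial turn-on transient (the 6 s discard removes the
motion-onset transient).  The streaming engine realises the same
recursions with `scipy.signal.lfilter` over time chunks; the per-step
`FilterState` functions are an independent implementation of the identical
recursion and the two are cross-checked in the test suite.

## Adaptive time-constant dynamics

The adapting high-pass follows
dτ_h/dt = K·(max_τh − τ_h) − g·S·(τ_h − min_τh), with K = 0.1 kHz,
S = LP_{τ_S}(|L′|) (τ_S = 500 ms) computed from the time derivative of the
delayed arm's low-pass signal, and τ_h clamped to [0, 500] ms.  For fixed
S the equation is linear, so each step integrates it exactly and
equilibrates at (K·max_τh + gS·min_τh)/(K + gS).  The drive gain g maps
signal scale to rate; its default g = K/s_half with s_half = 0.5 s⁻¹ puts
τ_h at midrange when S equals a nominal half dynamic range for unit-scale
LMC signals.  Each EMD carries two independent (τ_h, S) states, one per
half-detector arm, driven locally by its contralateral delayed signal.

## Calibration of the contrast-normalising variants

The saturation gain a = c/q̄₇₅ (c = 1) and the divisive guard
ε = 10⁻⁶·q̄₇₅ are estimated from a calibration pass of the front end over
the discarded first rotation, where q̄₇₅ is the mean over channels of each
channel's 75th percentile of signal magnitude.  Quartiles are estimated
from every 10th millisecond sample (an effective 100 Hz), which leaves
≥ 600 samples per channel and keeps the calibration buffer small; the
quantile estimate is statistically indistinguishable from the full-rate
one for these band-limited signals.

## Synthetic panoramas

The five habitat photographs behind the original analysis were never
deposited, so the generator produces surrogates carrying the statistics
the analysis actually depends on: a 1/f^β amplitude spectrum (β = 1)
synthesised in the 2D Fourier domain (hence exactly periodic in azimuth),
statistically distinct halves with the lower ("ground") half three times
the RMS contrast of the upper ("sky") half, clipping at zero luminance,
rescaling to the requested mean, and a fixed-point iteration that brings
the global RMS contrast within 0.5 % of the target (default 0.4, a
typical natural-scene value; real habitats span roughly an order of
magnitude around it).  Default raster 2880 × 560 px (0.125°/px) gives
10 px per receptor spacing and ≥ 4 px per prefilter σ.

What the surrogates do *not* emulate: the precise luminance distribution
of high-dynamic-range scenes (sun, specularities), oriented structure
(tree trunks, horizon clutter), vertical luminance gradients, and the
continuity of contrast statistics across the horizon.  Results that
depend mainly on geometry (azimuthal pooling of many phase-shifted EMD
signals) transfer well; results that depend on the vertical contrast
statistics of particular habitats (square-array reductions, absolute SD
values) are reproduced only approximately, and absolute SDs are not
comparable at all.

## Standard protocol and problem sizes

A run rotates the panorama at 60°/s in the preferred direction for 12 s
at 1 kHz (exactly two rotations) and discards the first rotation.
One-dimensional receptive-field analyses use a single receptor row at the
horizon with its own 288-EMD ring as full-field reference; 2D analyses
use the 56-row grid and its full 56 × 288 reference.  All receptive
fields of a sweep share one front-end/EMD pass and are reduced to
conductance sums chunk by chunk, so memory scales with grid size, not
trace length.  The test suite uses 1440 × 280 px panoramas (0.25°/px) and
shorter stimuli for everything except the headline checks, and the
square-array headline check uses three generator seeds; the acceptance
script uses the default raster and five seeds.

## Numerical choices and degenerate inputs

- Bilinear sampling wraps azimuth modulo 360°; receptor elevations must
  lie inside the panorama's row range (no vertical extrapolation).
- Naka-Rushton rejects negative luminance; I₀ estimation guards zeros
  with ε = 10⁻⁶ of the mean luminance and rejects all-zero images.
- τ ≤ 0 in a low-pass degenerates to a pass-through (α = 1), the correct
  limit for a fully adapted high-pass (τ_h = 0 kills the cross signal).
- Trace normalisation rejects |Z̄| < 10⁻⁹ (undefined relative units).
- Receptive-field placement rounds toward the horizon row and the centre
  azimuth when parity forces an off-centre block.
- The seam of Fourier-synthesised panoramas is exact by construction;
  step/sine fixtures are periodic by validation.

## Known limitations

- Rectangular (not hexagonal) receptor lattice, monochromatic input, no
  photoreceptor noise, and a static Naka-Rushton working point — matching
  the modelling scope, not the biology.
- The adaptive variant's drive gain g is a modelling choice (the source
  formulation leaves the proportionality open); steady-state results are
  insensitive to it, transient behaviour is not.
- Only horizontal constant-velocity rotation is implemented; no
  translation, no depth structure, no arbitrary optic-flow replay.
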