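# emdscope

Simulation of the fly motion-vision pathway — peripheral optics,
photoreceptor/lamina preprocessing, correlation-type elementary motion
detectors (EMDs), and gain-control dendritic integration by model
lobula-plate tangential cells (LPTCs) — for studying *pattern-dependent
response modulations*: the fluctuations a wide-field motion-sensitive
neuron shows even when a scene moves at perfectly constant velocity.

The package is aimed at computational neuroscientists who want to ask how
the **size and shape of a receptive field** trade velocity-signal quality
against the ability to localise pattern structure.  It provides synthetic
panoramic scenes with natural-image statistics, four standard EMD model
variants, rectangular and physiologically estimated (HSE-cell) receptive
fields, and the modulation statistics to compare them.

## Model

For a panoramic luminance field I(φ, θ) rotating at constant angular
velocity, each receptor (inter-receptor angle Φ = 1.25°) sees the scene
blurred by a Gaussian with FWHM Δρ = 1.64°, transduced by a Naka-Rushton
nonlinearity u = Iᵃ/(Iᵃ + I₀ᵃ) (a = 0.7, I₀ = geometric-mean luminance)
and band-pass filtered (LP τ_L = 8 ms, HP τ_H = 400 ms).  Neighbouring
receptor signals feed correlation-type EMDs (delay low-pass τ_lp = 40 ms,
multiplication, half-wave rectification into P⁺/P⁻).  A model LPTC pools
the half-detector outputs over its receptive field by gain control:

    Z = (Σ w·P⁺ − Σ w·P⁻) / (1 + Σ w·P⁺ + Σ w·P⁻)

Four correlator variants are available: `basic`, `adaptive` (adapting
high-pass in the cross arms), `saturation` (tanh compression of the input
lines), and `input_gain` (divisive normalisation by the running mean
absolute deviation).  Pattern-dependent modulation of a geometry (m × n
receptors) is quantified as

    N_t = Z_t / Z̄ − 1,     s = √( mean_t (N_t^{m,n} − N_t^{full})² )

the RMS deviation of the normalised response from the normalised
full-field response.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import emdscope as e

# a synthetic panorama with natural statistics: 1/f spectrum, ground 3x
# the contrast of the sky, global RMS contrast 0.4
p = e.generate_natural_panorama(e.SynthesisSpec(seed=1))
print(f"C_RMS = {e.rms_contrast(p):.3f}")

# one receptor row around the horizon; pool 1, 255 and all 288 EMDs
grid = e.ReceptorGrid.horizon()
rfs = [e.make_rect_rf(1, n, grid) for n in (2, 256, 288)]

# 12 s at 60 deg/s (two rotations), first rotation discarded
traces = e.run_simulation(p, "basic", rfs, grid=grid)
n2, n256, nfull = (e.normalize_response(t) for t in traces)
s2 = e.modulation_sd(n2, nfull)
s256 = e.modulation_sd(n256, nfull)
print(f"s(1x2) = {s2:.3f}   s(1x256) = {s256:.4f}   "
      f"reduction = {e.reduction_percentage(s2, s256):.1f}%")
```

Output:

```
C_RMS = 0.399
s(1x2) = 2.759   s(1x256) = 0.0406   reduction = 98.5%
```

A single EMD's response modulates by several times its own mean as scene
details pass its 1.25° viewpoint (s = 2.76 in relative response units);
pooling 255 EMDs across 320° of azimuth averages those phase-shifted
modulations away almost completely, leaving a response that tracks
velocity rather than pattern.  Elongating a receptive field along the
motion direction is far more effective than growing it vertically — a
square field with the same number of receptors retains several times more
modulation (`emdscope.sweep_2d` maps this out).

A thin CLI wraps the same functions, e.g.

```sh
emdscope synth --kind natural --seed 1 --out scene.tif
emdscope sweep --image scene.tif --variant basic --mode 1d --out sd.csv
```

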