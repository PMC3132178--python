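"""Quantification of pattern-dependent response modulations.

Responses to constant-velocity motion are made comparable across model
variants by normalising each trace to its own time mean,

    N_t = (Z_t - Zbar) / Zbar,

and the modulation left in a given receptive-field geometry is measured as
the root-mean-square deviation of its normalised trace from the normalised
full-field trace (the response of a cell pooling every channel),

    s = sqrt( mean_t (N_t^{m,n} - N_t^{full})^2 ).

By construction s = 0 when the field comprises the whole grid.  Population
(1/T) normalisation is used throughout for bit-reproducibility.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "normalize_response",
    "modulation_sd",
    "rms_contrast",
    "reduction_percentage",
    "summarize_sweep",
]


def _trace_array(trace) -> np.ndarray:
    z = getattr(trace, "z", trace)
    return np.asarray(z, dtype=float)


def normalize_response(trace) -> np.ndarray:
    """Relative response N_t = Z_t / Zbar - 1 (mean-zero by construction).

    Accepts a :class:`~emdscope.simulate.ResponseTrace` or a plain array.
    """
    z = _trace_array(trace)
    zbar = z.mean()
    if abs(zbar) < 1e-9:
        raise ValueError("mean response too close to zero; normalization undefined")
    return (z - zbar) / zbar


def modulation_sd(n_mn: np.ndarray, n_full: np.ndarray) -> float:
    """RMS deviation of a normalised trace from the full-field reference."""
    n_mn = np.asarray(n_mn, dtype=float)
    n_full = np.asarray(n_full, dtype=float)
    if n_mn.shape != n_full.shape:
        raise ValueError("traces must have equal lengths")
    return float(np.sqrt(np.mean((n_mn - n_full) ** 2)))


def rms_contrast(image) -> float:
    """Global RMS contrast: population std of luminance over its mean."""
    lum = np.asarray(getattr(image, "luminance", image), dtype=float)
    mean = lum.mean()
    if mean <= 0:
        raise ValueError("RMS contrast undefined for a zero-mean image")
    return float(lum.std() / mean)


def reduction_percentage(s_ref: float, s_test: float) -> float:
    """Percentage reduction of modulation SD relative to a reference: 100 (1 - s/s_ref)."""
    if s_ref <= 0:
        raise ValueError("reference SD must be positive")
    return 100.0 * (1.0 - s_test / s_ref)


def summarize_sweep(
    sweeps: Mapping[tuple[str, str], pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine per-(image, variant) SD matrices into tidy and mean tables.

    ``sweeps`` maps (image_id, variant) to a matrix as returned by the
    sweep functions (index = elevation or m, columns = n).  Returns the
    long-format table (image, variant, row, n, s) and the per-(variant,
    row, n) means over images, both deterministically ordered.
    """
    rows = []
    for (image, variant), mat in sorted(sweeps.items()):
        long = mat.stack().rename("s").reset_index()
        long.columns = ["row", "n", "s"]
        long.insert(0, "variant", variant)
        long.insert(0, "image", image)
        rows.append(long)
    table = pd.concat(rows, ignore_index=True)
    means = (
        table.groupby(["variant", "row", "n"], sort=True)["s"].mean().reset_index()
    )
    return table, means
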