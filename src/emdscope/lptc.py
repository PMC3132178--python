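"""Spatial pooling of EMD outputs by model tangential cells (LPTCs).

Dendritic integration follows the gain-control model: the weighted sums of
the rectified half-detector outputs act as excitatory and inhibitory
conductances driving the membrane toward reversal potentials E+ and E-,
normalised by the total conductance,

    Z = (E+ S+ - E- S-) / (G0 + S+ + S-),      S+- = sum_ij w_ij P+-_ij.

With E+ = E- = G0 = 1 this bounds |Z| < 1 for any stimulus extent and makes
the pooled response grow sublinearly with the number of active inputs.

Receptive fields are either unit-weight rectangles (m receptor rows by n
receptor columns, i.e. m x (n-1) EMD sites, or m x n with periodic closure
of the full ring) or the graded Gaussian sensitivity profile estimated for
the HSE cell, an equatorial horizontal-system LPTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ReceptorGrid

__all__ = [
    "ReceptiveField",
    "GainControlParams",
    "HseFieldParams",
    "gain_control_integrate",
    "make_rect_rf",
    "hse_weight_field",
    "emd_azimuths",
]


@dataclass
class GainControlParams:
    E_plus: float = 1.0
    E_minus: float = 1.0
    G0: float = 1.0

    def __post_init__(self) -> None:
        if self.G0 <= 0:
            raise ValueError("G0 must be positive")


@dataclass
class HseFieldParams:
    """Gaussian sensitivity profile of the model HSE receptive field.

    The azimuthal width is asymmetric about the centre: broad (120 deg) on
    the lateral side of the centre azimuth, narrow (25 deg) toward the
    frontal midline.
    """

    phi_c: float = -15.0
    theta_c: float = 2.0
    sigma_elev: float = 35.0
    sigma_az_lateral: float = 120.0
    sigma_az_frontal: float = 25.0

    def __post_init__(self) -> None:
        if min(self.sigma_elev, self.sigma_az_lateral, self.sigma_az_frontal) <= 0:
            raise ValueError("all sigmas must be positive")


@dataclass
class ReceptiveField:
    """Index set and weights of the EMD sites pooled by one model cell.

    ``row_indices``/``col_indices`` address sites of the EMD field
    (rows = receptor rows, columns = EMD columns); weights are in [0, 1].
    """

    row_indices: np.ndarray
    col_indices: np.ndarray
    weights: np.ndarray
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.row_indices = np.asarray(self.row_indices, dtype=int)
        self.col_indices = np.asarray(self.col_indices, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.row_indices.size == 0:
            raise ValueError("receptive field must contain at least one site")
        if not (self.row_indices.shape == self.col_indices.shape == self.weights.shape):
            raise ValueError("site indices and weights must have equal shapes")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.row_indices.size

    def dense_weights(self, field_shape: tuple[int, int]) -> np.ndarray:
        """Weights scattered onto the full (rows, n_emd) field, cached."""
        cached = getattr(self, "_dense", None)
        if cached is None or cached.shape != field_shape:
            dense = np.zeros(field_shape)
            dense[self.row_indices, self.col_indices] = self.weights
            object.__setattr__(self, "_dense", dense)
            cached = dense
        return cached

    def to_json(self) -> dict:
        return {
            "row_indices": self.row_indices.tolist(),
            "col_indices": self.col_indices.tolist(),
            "weights": self.weights.tolist(),
            "descriptor": self.descriptor,
        }


def gain_control_integrate(
    p_plus: np.ndarray,
    p_minus: np.ndarray,
    rf: ReceptiveField,
    gc: GainControlParams | None = None,
):
    """Gain-control pooling of one EMD field (or a time chunk thereof).

    Accepts fields of shape (rows, n_emd) or chunks (T, rows, n_emd) and
    returns Z (scalar or length-T vector).
    """
    gc = gc or GainControlParams()
    p_plus = np.asarray(p_plus, dtype=float)
    p_minus = np.asarray(p_minus, dtype=float)
    if rf.n_sites > 512:
        # large fields: one BLAS matvec over the dense weight image
        w = rf.dense_weights(p_plus.shape[-2:]).ravel()
        s_plus = p_plus.reshape(*p_plus.shape[:-2], -1) @ w
        s_minus = p_minus.reshape(*p_minus.shape[:-2], -1) @ w
    else:
        pp = p_plus[..., rf.row_indices, rf.col_indices]
        pm = p_minus[..., rf.row_indices, rf.col_indices]
        s_plus = pp @ rf.weights
        s_minus = pm @ rf.weights
    return (gc.E_plus * s_plus - gc.E_minus * s_minus) / (gc.G0 + s_plus + s_minus)


def emd_azimuths(grid: ReceptorGrid) -> np.ndarray:
    """Azimuth of each EMD site (midpoint of its receptor pair)."""
    if grid.periodic:
        return (grid.azimuths + grid.phi / 2.0) % 360.0
    return (grid.azimuths[:-1] + grid.azimuths[1:]) / 2.0


def _n_emd_cols(grid: ReceptorGrid) -> int:
    return grid.n_az if grid.periodic else grid.n_az - 1


def make_rect_rf(
    m_receptors: int,
    n_receptors: int,
    grid: ReceptorGrid,
    centre: tuple[float, float] = (180.0, 0.0),
) -> ReceptiveField:
    """Unit-weight rectangular field of m x (n-1) EMD sites.

    Sizes are counted in receptors: ``n_receptors`` horizontal receptors
    feed ``n_receptors - 1`` EMD columns, except that the full ring
    (n = n_az on a periodic grid) closes on itself and yields n_az columns.
    The block is centred at ``centre = (azimuth_deg, elevation_deg)``;
    when parity forces an off-centre placement the block is rounded toward
    the centre row/front.
    """
    if not 1 <= m_receptors <= grid.n_elev:
        raise ValueError(f"m must be in [1, {grid.n_elev}]")
    if not 2 <= n_receptors <= grid.n_az:
        raise ValueError(f"n must be in [2, {grid.n_az}]")
    az_c, el_c = centre
    n_emd = _n_emd_cols(grid)

    # rows: contiguous window of m rows centred on the requested elevation
    rc = float(np.interp(el_c, grid.elevations[::-1], np.arange(grid.n_elev)[::-1]))
    r0 = int(np.floor(rc - (m_receptors - 1) / 2.0 + 0.5))
    r0 = max(0, min(r0, grid.n_elev - m_receptors))
    rows = np.arange(r0, r0 + m_receptors)

    if grid.periodic and n_receptors == grid.n_az:
        cols = np.arange(n_emd)
    else:
        k = n_receptors - 1
        jc = (az_c % 360.0) / grid.phi - 0.5 if grid.periodic else float(
            np.interp(az_c, emd_azimuths(grid), np.arange(n_emd))
        )
        j0 = int(np.floor(jc - (k - 1) / 2.0 + 0.5))
        cols = np.arange(j0, j0 + k)
        if grid.periodic:
            cols = cols % n_emd
        elif cols[0] < 0 or cols[-1] >= n_emd:
            raise ValueError("receptive field exceeds the (non-periodic) grid")
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ReceptiveField(
        rr.ravel(),
        cc.ravel(),
        np.ones(rr.size),
        descriptor={"kind": "rect", "m": m_receptors, "n": n_receptors, "centre": list(centre)},
    )


def hse_weight_field(grid: ReceptorGrid, params: HseFieldParams | None = None) -> ReceptiveField:
    """Gaussian HSE sensitivity weights over all EMD sites of the grid.

    w(phi, theta) = exp(-[(phi-phi_c)^2 / (2 sigma_az^2)
                         + (theta-theta_c)^2 / (2 sigma_elev^2)])
    with sigma_az = 120 deg on the lateral side of the centre (azimuth
    difference of the same sign as the centre's offset from the frontal
    midline) and 25 deg on the frontal side; the peak weight is 1 at the
    centre.  Azimuth 0 is the frontal equatorial direction.
    """
    params = params or HseFieldParams()
    n_emd = _n_emd_cols(grid)
    az = emd_azimuths(grid)
    dphi = (az - params.phi_c + 180.0) % 360.0 - 180.0   # wrapped to [-180, 180)
    # lateral side: continuing away from the frontal midline past the centre
    lateral_sign = -1.0 if params.phi_c < 0 else 1.0
    sigma_az = np.where(
        dphi * lateral_sign > 0, params.sigma_az_lateral, params.sigma_az_frontal
    )
    dtheta = grid.elevations - params.theta_c
    w = np.exp(
        -(
            (dphi[None, :] ** 2) / (2.0 * sigma_az[None, :] ** 2)
            + (dtheta[:, None] ** 2) / (2.0 * params.sigma_elev ** 2)
        )
    )
    rr, cc = np.meshgrid(np.arange(grid.n_elev), np.arange(n_emd), indexing="ij")
    return ReceptiveField(
        rr.ravel(), cc.ravel(), w.ravel(), descriptor={"kind": "hse"}
    )
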