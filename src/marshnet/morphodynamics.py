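"""Sediment-bed and vegetation dynamics.

Bed elevation S follows a simplified balance of depth-saturating
sedimentation, shear-stress-driven erosion (reduced by vegetation cover and
proportional to S itself, since erodibility decreases with consolidation
depth) and slope-driven soil creep modelled as diffusion whose coefficient
is reduced by below-ground biomass. Vegetation stem density B follows
logistic growth damped by inundation depth, shear-stress mortality, and
clonal lateral expansion modelled as constant-coefficient diffusion.

Only the topographic diffusion term uses the conservative variable-
coefficient stencil (face diffusivities by arithmetic-mean interpolation);
the vegetation and eddy-viscosity diffusivities are spatially constant and
use the plain 5-point Laplacian.
"""

from __future__ import annotations

import numpy as np

from .params import GridSpec, ModelParams
from .hydrodynamics import DerivedFields, _interior_laplacian

__all__ = [
    "effective_depth",
    "sedimentation_term",
    "erosion_term",
    "sediment_diffusivity",
    "variable_diffusion",
    "laplacian",
    "sediment_tendency",
    "vegetation_tendency",
]


def effective_depth(h: np.ndarray, H_c: float) -> np.ndarray:
    """Effective water layer thickness h_e = h - H_c, a measure of
    inundation time. Requires the thin-film clamp to have been applied."""
    h = np.asarray(h)
    if np.any(h < H_c):
        raise ValueError("h < H_c encountered: apply the thin-film clamp "
                         "before computing the effective depth")
    return h - H_c


def sedimentation_term(h_e: np.ndarray, p: ModelParams) -> np.ndarray:
    """Sediment input rate S_in * h_e / (Q_s + h_e): zero on emergent
    terrain, saturating toward S_in in deep water, half-saturated at
    h_e = Q_s."""
    return p.Sin * h_e / (p.Qs + h_e)


def erosion_term(S: np.ndarray, B: np.ndarray, tau_b: np.ndarray,
                 p: ModelParams) -> np.ndarray:
    """Erosion rate E_S * (1 - p_E B/k) * S * tau_b / rho.

    Vegetation at carrying capacity shields a fraction p_E of the bare-bed
    erodibility; erodibility is proportional to elevation S above the
    consolidated reference bed.
    """
    return p.ES * (1.0 - p.pE * B / p.k) * S * tau_b / p.rho


def sediment_diffusivity(B: np.ndarray, p: ModelParams, D0=None):
    """Topographic diffusivity D_S = D_0 (1 - p_D B/k), reduced by
    below-ground biomass (root binding). ``D0`` may be a per-cell array for
    gradient configurations; default is the scalar ``p.D0``."""
    if D0 is None:
        D0 = p.D0
    return D0 * (1.0 - p.pD * np.asarray(B) / p.k)


def variable_diffusion(field: np.ndarray, D, dx: float,
                       dy: float | None = None) -> np.ndarray:
    """Conservative divergence of a variable-coefficient diffusive flux,
    div(D grad field), in flux form.

    Face diffusivities are the arithmetic means of the adjacent cell
    values, D_{i+1/2} = (D_i + D_{i+1})/2. Evaluated on the interior block;
    the boundary ring is zero. On a domain whose field carries zero-gradient
    edges the interior sum telescopes to zero exactly (discrete
    conservation).
    """
    if dy is None:
        dy = dx
    D = np.broadcast_to(np.asarray(D, dtype=float), field.shape)
    if np.any(D < 0):
        raise ValueError("diffusivity must be >= 0")
    out = np.zeros_like(field)
    # x-direction faces
    Dxf = 0.5 * (D[1:, :] + D[:-1, :])          # face (i+1/2, j)
    flux_x = Dxf * (field[1:, :] - field[:-1, :]) / dx
    out[1:-1, 1:-1] += (flux_x[1:, 1:-1] - flux_x[:-1, 1:-1]) / dx
    # y-direction faces
    Dyf = 0.5 * (D[:, 1:] + D[:, :-1])
    flux_y = Dyf * (field[:, 1:] - field[:, :-1]) / dy
    out[1:-1, 1:-1] += (flux_y[1:-1, 1:] - flux_y[1:-1, :-1]) / dy
    return out


def laplacian(field: np.ndarray, dx: float,
              dy: float | None = None) -> np.ndarray:
    """Constant-coefficient 5-point Laplacian on the interior block
    (boundary ring zero)."""
    if dy is None:
        dy = dx
    out = np.zeros_like(field)
    out[1:-1, 1:-1] = _interior_laplacian(field, dx, dy)
    return out


def sediment_tendency(h: np.ndarray, S: np.ndarray, B: np.ndarray,
                      fields: DerivedFields, p: ModelParams,
                      grid: GridSpec) -> np.ndarray:
    """dS/dt = sedimentation - erosion + div(D_S grad S).

    Pointwise terms on the full grid, the diffusive term on the interior.
    S is deliberately not floored at zero: erosion is proportional to S and
    self-limits, and diffusion near the fixed open-boundary bed may produce
    small negative excursions which are retained.
    """
    out = sedimentation_term(fields.h_e, p) - erosion_term(S, B, fields.tau_b, p)
    out += variable_diffusion(S, fields.D_S, grid.dx, grid.dy)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite sediment tendency")
    return out


def vegetation_tendency(h: np.ndarray, B: np.ndarray,
                        fields: DerivedFields, p: ModelParams,
                        grid: GridSpec) -> np.ndarray:
    """dB/dt = r B (1 - B/k) Q_q/(Q_q + h_e) - E_B B tau_b/rho
    + D_B Laplacian(B).

    Logistic growth is damped with inundation (half-rate at h_e = Q_q);
    mortality scales with bed shear stress. B = 0 is an exact fixed point:
    establishment only occurs in the initial condition, never spontaneously.
    """
    growth = p.r * B * (1.0 - B / p.k) * (p.Qq / (p.Qq + fields.h_e))
    mortality = p.EB * B * fields.tau_b / p.rho
    out = growth - mortality
    out[1:-1, 1:-1] += p.DB * _interior_laplacian(B, grid.dx, grid.dy)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite vegetation tendency")
    return out
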