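"""Depth-averaged shallow-water hydrodynamics on the marsh platform.

The flow model is a steady continuous ebb discharge: a spatially uniform
water source H_in feeds the continuity equation and the water drains through
the single open boundary at i = n_x - 1. Waves and the flood phase are not
modelled. A thin-film floor on the water layer (h >= H_c) keeps the momentum
equations defined on emergent terrain.

All tendency routines use forward-Euler-compatible central differences.
Spatial-derivative terms are evaluated on the interior ring only (boundary
cells are governed by the boundary-condition routines); purely pointwise
terms (source, friction) are evaluated on the full grid.

Grids are (n_x, n_y) row-major with i shoreward (down-slope, axis 0) and j
alongshore (axis 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GridSpec, ModelParams

__all__ = [
    "DerivedFields",
    "apply_thin_film",
    "manning_n",
    "chezy",
    "bed_shear",
    "compute_derived",
    "momentum_tendencies",
    "continuity_tendency",
    "apply_velocity_bcs",
    "apply_scalar_bcs",
    "open_boundary_outflux",
]


@dataclass
class DerivedFields:
    """Diagnostic fields computed from the prognostic state.

    h_e     effective water depth h - H_c (m), a measure of inundation time
    n       Manning roughness (s m^-1/3), linear in vegetation density
    C_z     Chezy coefficient h^(1/6)/n (m^1/2 s^-1)
    tau_bx, tau_by, tau_b   bed shear stress components and magnitude (N m^-2)
    D_S     vegetation-reduced topographic diffusivity (m^2 s^-1)
    eta     water surface elevation h + S (m)
    """

    h_e: np.ndarray
    n: np.ndarray
    C_z: np.ndarray
    tau_bx: np.ndarray
    tau_by: np.ndarray
    tau_b: np.ndarray
    D_S: np.ndarray
    eta: np.ndarray


def apply_thin_film(h: np.ndarray, H_c: float) -> np.ndarray:
    """Wetting/drying floor: h can never be thinner than the critical layer
    H_c. Elementwise max; idempotent."""
    if H_c <= 0:
        raise ValueError(f"H_c must be > 0, got {H_c}")
    return np.maximum(h, H_c)


def manning_n(B: np.ndarray, p: ModelParams) -> np.ndarray:
    """Manning roughness, increasing linearly with stem density from the
    bare-bed value n_b to the fully vegetated value n_v at B = k."""
    if p.k == 0:
        raise ValueError("carrying capacity k must be nonzero")
    return p.nb + (p.nv - p.nb) * (np.asarray(B) / p.k)


def chezy(h: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Chezy coefficient from Manning's formulation, C_z = h^(1/6) / n."""
    h = np.asarray(h)
    n = np.asarray(n)
    if np.any(h <= 0) or np.any(n <= 0):
        raise ValueError("chezy requires h > 0 and n > 0 everywhere")
    return h ** (1.0 / 6.0) / n


def bed_shear(u: np.ndarray, v: np.ndarray, C_z: np.ndarray,
              rho: float, g: float = 9.81,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadratic bed friction: tau/rho = (g/C_z^2) * |U| * (u, v, |U|).

    Returns the stress components and magnitude in N m^-2. The component
    signs follow the velocity, so friction always opposes the motion when
    inserted with a minus sign in the momentum balance.
    """
    speed = np.sqrt(u * u + v * v)
    coef = rho * g / (C_z * C_z) * speed
    return coef * u, coef * v, coef * speed


def compute_derived(h: np.ndarray, u: np.ndarray, v: np.ndarray,
                    S: np.ndarray, B: np.ndarray, p: ModelParams,
                    D0=None) -> DerivedFields:
    """All diagnostic fields for a (clamped) state. ``D0`` may override the
    scalar bare-soil diffusivity with a per-cell array (gradient runs)."""
    from .morphodynamics import sediment_diffusivity  # local to avoid cycle

    n = manning_n(B, p)
    C_z = chezy(h, n)
    tau_bx, tau_by, tau_b = bed_shear(u, v, C_z, p.rho, p.g)
    return DerivedFields(
        h_e=h - p.Hc,
        n=n,
        C_z=C_z,
        tau_bx=tau_bx,
        tau_by=tau_by,
        tau_b=tau_b,
        D_S=sediment_diffusivity(B, p, D0=D0),
        eta=h + S,
    )


def _interior_gradient_x(f: np.ndarray, dx: float) -> np.ndarray:
    """Central difference along axis 0 on the interior block."""
    return (f[2:, 1:-1] - f[:-2, 1:-1]) / (2.0 * dx)


def _interior_gradient_y(f: np.ndarray, dy: float) -> np.ndarray:
    return (f[1:-1, 2:] - f[1:-1, :-2]) / (2.0 * dy)


def _interior_laplacian(f: np.ndarray, dx: float, dy: float) -> np.ndarray:
    return ((f[2:, 1:-1] - 2.0 * f[1:-1, 1:-1] + f[:-2, 1:-1]) / (dx * dx)
            + (f[1:-1, 2:] - 2.0 * f[1:-1, 1:-1] + f[1:-1, :-2]) / (dy * dy))


def momentum_tendencies(h: np.ndarray, u: np.ndarray, v: np.ndarray,
                        S: np.ndarray, B: np.ndarray, p: ModelParams,
                        grid: GridSpec, fields: DerivedFields | None = None,
                        advection: str = "central",
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Tendencies du/dt, dv/dt of the depth-averaged momentum equations.

    Terms: pressure gradient -g d(h+S)/dax, momentum advection, quadratic
    bed friction -tau/(rho h), and eddy-viscosity mixing D_U * Laplacian
    (D_U spatially constant). ``h`` must already be clamped (h >= H_c).

    ``advection`` selects "central" (the canonical scheme) or "upwind"
    (first-order, provided as a robustness escape hatch only).

    Spatial-derivative terms are evaluated on the interior; boundary cells
    carry only the pointwise friction term and are overwritten by
    :func:`apply_velocity_bcs` in any full step.
    """
    if advection not in ("central", "upwind"):
        raise ValueError(f"unknown advection scheme {advection!r}")
    if fields is None:
        fields = compute_derived(h, u, v, S, B, p)

    dudt = -fields.tau_bx / (p.rho * h)
    dvdt = -fields.tau_by / (p.rho * h)

    eta = fields.eta
    ui = u[1:-1, 1:-1]
    vi = v[1:-1, 1:-1]

    if advection == "central":
        dudx = _interior_gradient_x(u, grid.dx)
        dudy = _interior_gradient_y(u, grid.dy)
        dvdx = _interior_gradient_x(v, grid.dx)
        dvdy = _interior_gradient_y(v, grid.dy)
    else:  # upwind
        dudx = _upwind_gradient_x(u, ui, grid.dx)
        dudy = _upwind_gradient_y(u, vi, grid.dy)
        dvdx = _upwind_gradient_x(v, ui, grid.dx)
        dvdy = _upwind_gradient_y(v, vi, grid.dy)

    dudt[1:-1, 1:-1] += (-p.g * _interior_gradient_x(eta, grid.dx)
                         - ui * dudx - vi * dudy
                         + p.DU * _interior_laplacian(u, grid.dx, grid.dy))
    dvdt[1:-1, 1:-1] += (-p.g * _interior_gradient_y(eta, grid.dy)
                         - ui * dvdx - vi * dvdy
                         + p.DU * _interior_laplacian(v, grid.dx, grid.dy))

    if not (np.all(np.isfinite(dudt)) and np.all(np.isfinite(dvdt))):
        raise FloatingPointError(
            "non-finite momentum tendency (numerical instability); "
            f"max |u|={np.nanmax(np.abs(u)):.3g}, "
            f"max |v|={np.nanmax(np.abs(v)):.3g}, "
            f"min h={np.nanmin(h):.3g}")
    return dudt, dvdt


def _upwind_gradient_x(f, carrier, dx):
    fwd = (f[2:, 1:-1] - f[1:-1, 1:-1]) / dx
    bwd = (f[1:-1, 1:-1] - f[:-2, 1:-1]) / dx
    return np.where(carrier > 0, bwd, fwd)


def _upwind_gradient_y(f, carrier, dy):
    fwd = (f[1:-1, 2:] - f[1:-1, 1:-1]) / dy
    bwd = (f[1:-1, 1:-1] - f[1:-1, :-2]) / dy
    return np.where(carrier > 0, bwd, fwd)


def continuity_tendency(h: np.ndarray, u: np.ndarray, v: np.ndarray,
                        p: ModelParams, grid: GridSpec) -> np.ndarray:
    """dh/dt = -d(uh)/dx - d(vh)/dy + H_in, flux-form central differences.

    The uniform source H_in is applied on the full grid; the flux divergence
    on the interior only.
    """
    Fx = u * h
    Fy = v * h
    dhdt = np.full_like(h, p.Hin)
    dhdt[1:-1, 1:-1] -= (_interior_gradient_x(Fx, grid.dx)
                         + _interior_gradient_y(Fy, grid.dy))
    if not np.all(np.isfinite(dhdt)):
        raise FloatingPointError("non-finite continuity tendency")
    return dhdt


def apply_velocity_bcs(u: np.ndarray, v: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Impose the velocity boundary conditions in place.

    Open outflow boundary i = n_x-1: constant gradient (d2/dx2 = 0), i.e.
    linear extrapolation of u and v. Closed boundary i = 0: reflecting flow,
    normal component sign-flipped, tangential copied. Closed alongshore
    boundaries j = 0 and j = n_y-1: same with the roles of u and v swapped.
    Corner cells are finalized by the alongshore conditions.
    """
    if u.shape[0] < 3 or u.shape[1] < 3:
        raise ValueError(f"grid too small for boundary conditions: {u.shape}")
    # open outflow at i = n_x - 1
    u[-1, :] = 2.0 * u[-2, :] - u[-3, :]
    v[-1, :] = 2.0 * v[-2, :] - v[-3, :]
    # closed landward boundary i = 0
    u[0, :] = -u[1, :]
    v[0, :] = v[1, :]
    # closed alongshore boundaries (normal component is v here)
    u[:, 0] = u[:, 1]
    v[:, 0] = -v[:, 1]
    u[:, -1] = u[:, -2]
    v[:, -1] = -v[:, -2]
    return u, v


def apply_scalar_bcs(field: np.ndarray, which: str) -> np.ndarray:
    """Impose scalar boundary conditions in place.

    Zero gradient at every closed boundary for h, S and B. At the open
    outflow boundary, zero gradient for h and B; for S the bed is fixed at
    the reference level (erosion and deposition in balance), S = 0.
    """
    if which not in ("h", "S", "B"):
        raise ValueError(f"unknown field tag {which!r}")
    field[0, :] = field[1, :]
    if which == "S":
        field[-1, :] = 0.0
    else:
        field[-1, :] = field[-2, :]
    field[:, 0] = field[:, 1]
    field[:, -1] = field[:, -2]
    return field


def open_boundary_outflux(h: np.ndarray, u: np.ndarray,
                          grid: GridSpec) -> float:
    """Volume flux (m^3/s) leaving through the open boundary, measured as
    the central-difference telescoping remainder of the interior flux
    divergence: sum_j (F[n_x-1, j] + F[n_x-2, j]) / 2 * dy with F = u h.

    With the reflecting closed-boundary conditions the remainders at the
    three closed boundaries vanish identically, so this is the exact
    counterpart of the discrete interior mass budget.
    """
    F = u * h
    return float(np.sum(0.5 * (F[-1, 1:-1] + F[-2, 1:-1])) * grid.dy)
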