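"""Domain grid, model parameters, validation and parameter derivations.

The parameter set describes an intertidal platform drained by a steady ebb
discharge: shallow-water flow over an erodible bed whose elevation is set by
a sedimentation/erosion/soil-creep balance, coupled to vegetation that raises
bed roughness (Manning n), shields sediment from erosion (p_E) and binds soil
against slope-driven creep (p_D). All quantities are SI.

Several parameters are not taken from literature directly but derived from a
small number of field-scale facts (tidal prism drained per M2 tide, reference
sediment input per tide); the ``derive_*`` functions reproduce those
calculations and report them at the conventional number of significant
figures alongside the raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "M2_PERIOD_S",
    "SECONDS_PER_YEAR",
    "GridSpec",
    "ModelParams",
    "GradientSpec",
    "validate_params",
    "derive_m2_seconds",
    "derive_end_time_periods",
    "derive_discharge_velocity",
    "derive_sediment_input",
    "derive_erosion_rate_estimate",
    "round_sig",
]

#: Duration of one M2 (principal lunar semi-diurnal) tidal period: 12.42 h.
#: Fixed, not configurable, so the morphological acceleration factor and the
#: end-time bookkeeping always refer to the same clock.
M2_PERIOD_S: float = 12.42 * 3600.0  # = 44712.0 s

#: Julian year (365.25 d); the only year length that makes 50 yr equal
#: 35290 M2 periods after rounding.
SECONDS_PER_YEAR: float = 365.25 * 86400.0


def round_sig(x: float, n_digits: int) -> float:
    """Round ``x`` to ``n_digits`` significant figures (decimal rounding of
    the mantissa). Returns 0.0 unchanged."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, n_digits - 1 - exponent)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular staggered-free grid.

    Index ``i`` runs shoreward (down-slope) 0..n_x-1 with the open outflow
    boundary at ``i = n_x - 1``; index ``j`` runs alongshore 0..n_y-1 with
    both alongshore boundaries closed.
    """

    n_x: int = 1024
    n_y: int = 2048
    dx: float = 0.5  # m
    dy: float = 0.5  # m

    @property
    def l_x(self) -> float:
        return self.n_x * self.dx

    @property
    def l_y(self) -> float:
        return self.n_y * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def validate(self) -> "GridSpec":
        errors = []
        if self.n_x < 3:
            errors.append(f"n_x must be >= 3, got {self.n_x}")
        if self.n_y < 3:
            errors.append(f"n_y must be >= 3, got {self.n_y}")
        if self.dx <= 0:
            errors.append(f"dx must be > 0, got {self.dx}")
        if self.dy <= 0:
            errors.append(f"dy must be > 0, got {self.dy}")
        if errors:
            raise ValueError("invalid GridSpec: " + "; ".join(errors))
        return self


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical parameters of the biogeomorphic model.

    Defaults are the default-simulation values. Attribute names follow the
    conventional symbols; the config-file keys carry explicit units (see
    :mod:`marshnet.io`).
    """

    dt: float = 0.0125          # s, hydrodynamic time step
    phi: float = M2_PERIOD_S    # morphological acceleration (s per hydro s)
    t_end_years: float = 50.0   # yr, simulated (accelerated) duration
    D0: float = 1.0e-7          # m2/s, bare-soil topographic diffusivity
    DB: float = 6.0e-9          # m2/s, vegetation clonal-expansion diffusivity
    DU: float = 0.5             # m2/s, turbulent eddy viscosity
    ES: float = 2.5e-4          # s/m2, bare-bed sediment erosion rate
    EB: float = 1.0e-5          # s/m2, vegetation mortality per unit stress
    g: float = 9.81             # m/s2
    H0: float = 0.02            # m, initial water layer thickness
    Hc: float = 1.0e-3          # m, critical (thin-film) water layer
    Hin: float = 1.0e-5         # m/s, steady ebb discharge source
    k: float = 1500.0           # 1/m2, vegetation carrying capacity
    nb: float = 0.016           # s m^-1/3, Manning n of bare sediment
    nv: float = 0.2             # s m^-1/3, Manning n at carrying capacity
    pD: float = 0.99            # -, diffusivity reduction at full vegetation
    pE: float = 0.9             # -, erosion reduction at full vegetation
    pest: float = 0.002         # -, seedling establishment probability
    Qq: float = 0.02            # m, depth halving vegetation growth
    Qs: float = 6.0e-4          # m, depth halving sediment input
    rho: float = 1000.0         # kg/m3, water density
    r: float = 3.2e-8           # 1/s, intrinsic plant growth rate (~1/yr)
    Sin: float = 5.0e-9         # m/s, maximal sediment input rate

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_params(p: ModelParams) -> ModelParams:
    """Check every parameter invariant; raise ``ValueError`` naming all
    violated fields, or return ``p`` unchanged."""
    errors: list[str] = []
    nonneg = ["phi", "t_end_years", "D0", "DB", "DU", "ES", "EB", "g",
              "H0", "Hc", "Hin", "k", "nb", "nv", "Qq", "Qs", "rho", "r",
              "Sin"]
    for name in nonneg:
        v = getattr(p, name)
        if not (v >= 0):
            errors.append(f"{name} must be >= 0, got {v}")
    if not (p.dt > 0):
        errors.append(f"dt must be > 0, got {p.dt}")
    if not (0 <= p.pD < 1):
        errors.append(f"pD must satisfy 0 <= pD < 1, got {p.pD}")
    if not (0 <= p.pE <= 1):
        errors.append(f"pE must satisfy 0 <= pE <= 1, got {p.pE}")
    if not (0 <= p.pest <= 1):
        errors.append(f"pest must satisfy 0 <= pest <= 1, got {p.pest}")
    if not (p.Hc < p.H0):
        errors.append(f"Hc must be < H0, got Hc={p.Hc}, H0={p.H0}")
    if not (p.nb <= p.nv):
        errors.append(f"nb must be <= nv, got nb={p.nb}, nv={p.nv}")
    if not (p.phi >= 1):
        errors.append(f"phi must be >= 1, got {p.phi}")
    if errors:
        raise ValueError("invalid ModelParams: " + "; ".join(errors))
    return p


@dataclass(frozen=True)
class GradientSpec:
    """Endpoints of a log-spaced gradient in bare-soil diffusivity D0,
    used to vary the relative biogeomorphic feedback strength."""

    D0_min: float = 1.0e-7  # m2/s
    D0_max: float = 2.0e-4  # m2/s
    axis: str = "y"         # coordinate along which D0 varies

    def __post_init__(self) -> None:
        if not (0 < self.D0_min <= self.D0_max):
            raise ValueError(
                f"require 0 < D0_min <= D0_max, got "
                f"D0_min={self.D0_min}, D0_max={self.D0_max}")
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")


# ---------------------------------------------------------------------------
# Parameter derivations
# ---------------------------------------------------------------------------

def derive_m2_seconds() -> float:
    """Number of seconds in one M2 tidal period (12.42 h) — the value of the
    morphological acceleration factor in the default configuration."""
    return M2_PERIOD_S


def derive_end_time_periods(years: float) -> int:
    """Simulated end time expressed as a whole number of M2 tidal periods.

    Uses Julian years (365.25 d): 50 yr -> 35290 periods.
    """
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    return round(years * SECONDS_PER_YEAR / M2_PERIOD_S)


def derive_discharge_velocity(drained_depth: float,
                              period: float = M2_PERIOD_S,
                              ) -> tuple[float, float]:
    """Tidally averaged discharge velocity from the prism drained per tide.

    A tidal flat that drains ``drained_depth`` metres of water column per
    tidal ``period`` discharges at drained_depth/period m/s. Returns
    ``(raw, rounded_2sf)``; 0.75 m per M2 tide gives 1.7e-5 m/s (2 s.f.).
    """
    if period <= 0:
        raise ValueError(f"period must be > 0, got {period}")
    raw = drained_depth / period
    return raw, round_sig(raw, 2)


#: Reference maximal sediment input used in the S_in derivation: 0.2 cm per
#: tide, reduced by a factor 10 to account for the shallower steady-discharge
#: water column.
_REFERENCE_INPUT_M_PER_TIDE: float = 0.002 / 10.0
#: Reference erosion per tide (same 10x reduction) used for the E_S estimate.
_REFERENCE_EROSION_PER_TIDE: float = 0.03 / 10.0


def derive_sediment_input(p: ModelParams) -> tuple[float, float]:
    """Maximal sediment input rate S_in.

    The depth-saturating input S_in * h_e/(Q_s+h_e), evaluated at the initial
    depth h = H_0, must equal the (ten-fold reduced) reference input of
    0.02 cm per M2 tide. Returns ``(raw, rounded_1sf)``; defaults give
    5e-9 m/s (1 s.f.).
    """
    h_e = p.H0 - p.Hc
    depth_factor = h_e / (p.Qs + h_e) if (p.Qs + h_e) != 0 else 0.0
    if depth_factor == 0:
        raise ValueError("Q_s + h_e must be nonzero with h_e = H0 - Hc > 0")
    raw = (_REFERENCE_INPUT_M_PER_TIDE / M2_PERIOD_S) / depth_factor
    return raw, round_sig(raw, 1)


def derive_erosion_rate_estimate(bed_slope: float,
                                 p: ModelParams) -> float:
    """Order-of-magnitude estimate of the bare-bed erosion rate E_S.

    Under a homogeneous equilibrium the momentum balance reduces to pressure
    gradient vs bed friction, 0 = g*beta - tau_bx/(rho h), so tau_b/rho =
    g*beta*H_0 for a sub-sediment bed slope beta. Equating E_S*(tau_b/rho)
    with the reference erosion of 0.003 per tide yields the estimate. The
    stored default ``ModelParams.ES = 2.5e-4`` is the empirically tuned
    value; this function documents the derivation only.
    """
    if bed_slope <= 0:
        raise ValueError(f"bed_slope must be > 0, got {bed_slope}")
    if p.H0 <= 0:
        raise ValueError(f"H0 must be > 0, got {p.H0}")
    tau_over_rho = p.g * bed_slope * p.H0
    return (_REFERENCE_EROSION_PER_TIDE / M2_PERIOD_S) / tau_over_rho
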