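"""Run orchestration: initialization, the per-step update cycle with
morphological acceleration, diffusivity-gradient configuration,
checkpointing and summary bookkeeping.

The update cycle per hydrodynamic time step dt is strictly ordered:

1. thin-film clamp on h;
2. momentum tendencies from the old state;
3. explicit update of u and v;
4. velocity boundary conditions;
5. dh/dt, dS/dt, dB/dt evaluated with the *updated* velocities;
6. h += dh dt; S += dS dt Phi; B += dB dt Phi (B then clamped to [0, k]);
7. scalar boundary conditions; the morphological clock advances by dt Phi.

The acceleration factor Phi scales the slow bed/vegetation tendencies so
that one hydrodynamic second advances the morphology by Phi seconds; with
the default Phi equal to one M2 tidal period, "simulated time" always means
morphologically accelerated time. Because the bed equation carries no
advective terms, acceleration does not interact with the CFL limit.

Execution is serial/vectorized; any tiling or parallel variant must
reproduce these results bit-exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (GridSpec, GradientSpec, ModelParams, SECONDS_PER_YEAR,
                     validate_params)
from . import hydrodynamics as hyd
from . import morphodynamics as morph

__all__ = [
    "SimState",
    "RunConfig",
    "Trajectory",
    "initialize_state",
    "d0_profile",
    "d0_stations",
    "d0_field",
    "step",
    "run",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass
class SimState:
    """Prognostic model state on the grid.

    t is the morphological (accelerated) clock in seconds. h is the water
    layer thickness, u/v the depth-averaged velocity components, S the
    sediment bed elevation above the reference bed, B the vegetation stem
    density.
    """

    t: float
    h: np.ndarray
    u: np.ndarray
    v: np.ndarray
    S: np.ndarray
    B: np.ndarray
    #: fast-engine inverse-cube-root cache of h; carried through snapshots
    #: and checkpoints so a resumed run reproduces an uninterrupted one
    #: bit-for-bit. Not part of the physical state.
    fric_cache: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape

    @property
    def t_years(self) -> float:
        return self.t / SECONDS_PER_YEAR

    def copy(self) -> "SimState":
        cache = None if self.fric_cache is None else self.fric_cache.copy()
        return SimState(self.t, self.h.copy(), self.u.copy(),
                        self.v.copy(), self.S.copy(), self.B.copy(), cache)

    def check_finite(self) -> None:
        for name in ("h", "u", "v", "S", "B"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(
                    f"non-finite values in field {name} at t = "
                    f"{self.t_years:.4f} yr")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit."""

    grid: GridSpec = field(default_factory=GridSpec)
    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0
    snapshot_every_years: float = 1.0
    checkpoint_path: str | None = None
    gradient: GradientSpec | None = None   # per-column D0 instead of scalar
    veg_dynamics: bool = True              # False: dB/dt = 0 (B frozen)
    advection: str = "central"
    engine: str = "auto"                   # auto | numba | numpy
    nan_check_every: int = 1000
    log_every: int = 0                     # 0 disables progress logging

    def validate(self) -> "RunConfig":
        self.grid.validate()
        validate_params(self.params)
        if self.snapshot_every_years <= 0:
            raise ValueError("snapshot cadence must be > 0")
        if self.engine not in ("auto", "numba", "numpy"):
            raise ValueError(f"unknown engine {self.engine!r}")
        return self

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)


def initialize_state(cfg: RunConfig) -> SimState:
    """Initial condition: flat horizontal bed (S = 0), still water of
    thickness H_0, and sparse random vegetation tussocks.

    Each grid cell draws one uniform [0,1) sample (row-major order from a
    single seeded generator, so placement is stable across grid layouts);
    cells with draw < p_est start at carrying capacity, one cell per
    tussock; all other cells start bare.
    """
    cfg.validate()
    p = cfg.params
    shape = cfg.grid.shape
    rng = np.random.default_rng(cfg.seed)
    draws = rng.random(shape)
    B = np.where(draws < p.pest, p.k, 0.0)
    return SimState(
        t=0.0,
        h=np.full(shape, p.H0, dtype=float),
        u=np.zeros(shape),
        v=np.zeros(shape),
        S=np.zeros(shape),
        B=B.astype(float),
    )


# ---------------------------------------------------------------------------
# Diffusivity gradient
# ---------------------------------------------------------------------------

def d0_profile(y, spec: GradientSpec, l_y: float):
    """Log-spaced diffusivity profile between D0_min at y = 0 and D0_max at
    y = l_y: exp((ln D0_max - ln D0_min) y/l_y + ln D0_min)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > l_y):
        raise ValueError("y must lie within [0, l_y]")
    ln_min = math.log(spec.D0_min)
    ln_max = math.log(spec.D0_max)
    out = np.exp((ln_max - ln_min) * y / l_y + ln_min)
    return float(out) if out.ndim == 0 else out


def d0_stations(spec: GradientSpec, n: int = 16) -> np.ndarray:
    """D0 values at n equidistant stations along the gradient, used to split
    a gradient configuration into separate fixed-D0 runs (adjacent areas of
    a single gradient run would interfere)."""
    if n < 1:
        raise ValueError("need at least one station")
    if n == 1:
        return np.array([spec.D0_min])
    y = np.linspace(0.0, 1.0, n)
    return d0_profile(y, spec, 1.0)


def d0_field(grid: GridSpec, spec: GradientSpec) -> np.ndarray:
    """Per-cell D0 array for an in-domain gradient run (D0 varying along
    the chosen axis, constant along the other)."""
    if spec.axis == "y":
        coords = np.arange(grid.n_y) * grid.dy
        row = d0_profile(coords, spec, grid.l_y)
        return np.broadcast_to(row, grid.shape).copy()
    coords = np.arange(grid.n_x) * grid.dx
    col = d0_profile(coords, spec, grid.l_x)
    return np.broadcast_to(col[:, None], grid.shape).copy()


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def step(state: SimState, p: ModelParams, grid: GridSpec, *,
         D0=None, veg_dynamics: bool = True, advection: str = "central",
         audit: dict | None = None) -> SimState:
    """Advance the state by one hydrodynamic time step (in place).

    ``audit``, if given, accumulates 'clamped_volume' (m^3 of water added
    by the thin-film floor, so mass budgets can exclude it) and records the
    open-boundary 'outflux' (m^3/s) of this step.
    """
    h, u, v, S, B = state.h, state.u, state.v, state.S, state.B

    # (1) wetting/drying floor
    if audit is not None:
        deficit = p.Hc - h
        np.maximum(deficit, 0.0, out=deficit)
        audit["clamped_volume"] = (audit.get("clamped_volume", 0.0)
                                   + float(deficit.sum()) * grid.cell_area)
    np.maximum(h, p.Hc, out=h)

    # (2) momentum tendencies from the old state
    fields = hyd.compute_derived(h, u, v, S, B, p, D0=D0)
    dudt, dvdt = hyd.momentum_tendencies(h, u, v, S, B, p, grid,
                                         fields=fields, advection=advection)

    # (3) velocity update, (4) velocity boundary conditions
    u += dudt * p.dt
    v += dvdt * p.dt
    hyd.apply_velocity_bcs(u, v)

    # (5) scalar tendencies with the updated velocities
    fields.tau_bx, fields.tau_by, fields.tau_b = hyd.bed_shear(
        u, v, fields.C_z, p.rho, p.g)
    if audit is not None:
        audit["outflux"] = hyd.open_boundary_outflux(h, u, grid)
    dhdt = hyd.continuity_tendency(h, u, v, p, grid)
    dSdt = morph.sediment_tendency(h, S, B, fields, p, grid)
    dBdt = (morph.vegetation_tendency(h, B, fields, p, grid)
            if veg_dynamics else None)

    # (6) explicit updates; bed and vegetation morphologically accelerated
    h += dhdt * p.dt
    S += dSdt * (p.dt * p.phi)
    if dBdt is not None:
        B += dBdt * (p.dt * p.phi)
        np.clip(B, 0.0, p.k, out=B)

    # (7) scalar boundary conditions and clock
    hyd.apply_scalar_bcs(h, "h")
    hyd.apply_scalar_bcs(S, "S")
    hyd.apply_scalar_bcs(B, "B")
    state.t += p.dt * p.phi
    return state


@dataclass
class Trajectory:
    """Checkpointed output of :func:`run`: state snapshots at the configured
    cadence plus a per-snapshot summary table."""

    config: RunConfig
    snapshots: list[tuple[float, SimState]]
    summary: pd.DataFrame

    @property
    def final_state(self) -> SimState:
        return self.snapshots[-1][1]


def _summary_row(state: SimState, audit: dict) -> dict:
    years = state.t_years
    mean_S = float(state.S.mean())
    return {
        "t_years": years,
        "mean_B": float(state.B.mean()),
        "mean_S": mean_S,
        "mean_accretion_rate_m_per_yr": mean_S / years if years > 0 else 0.0,
        "clamped_volume_m3": audit.get("clamped_volume", 0.0),
    }


def run(cfg: RunConfig, duration_years: float | None = None,
        state: SimState | None = None) -> Trajectory:
    """Iterate :func:`step` until the morphological clock reaches the
    requested duration, emitting snapshots and a summary series.

    ``state`` may be a checkpointed state to resume from; resuming
    reproduces an uninterrupted run bit-for-bit (the RNG is only used at
    initialization, and a snapshot captures the full prognostic state).
    """
    cfg.validate()
    p = cfg.params
    grid = cfg.grid
    if duration_years is None:
        duration_years = p.t_end_years
    D0 = d0_field(grid, cfg.gradient) if cfg.gradient is not None else None

    if state is None:
        state = initialize_state(cfg)
    audit: dict = {"clamped_volume": 0.0}

    # Engine resolution: the fused kernel replicates the reference numpy
    # step arithmetic exactly; "auto" uses it whenever numba imports. The
    # central-difference scheme is the only one fused (the upwind escape
    # hatch always runs on the reference path).
    from ._kernel import HAVE_NUMBA, StepScratch, fused_step
    use_fast = (cfg.engine in ("auto", "numba") and HAVE_NUMBA
                and cfg.advection == "central")
    if cfg.engine == "numba" and not use_fast:
        raise RuntimeError("numba engine requested but unavailable "
                           "(or incompatible with the advection scheme)")
    if use_fast:
        D0_arr = (D0 if D0 is not None
                  else np.full(grid.shape, p.D0, dtype=float))
        scratch = StepScratch(grid.shape)
        if state.fric_cache is not None:
            scratch.icbrt = state.fric_cache.copy()
        state.fric_cache = scratch.icbrt

    snapshots: list[tuple[float, SimState]] = []
    rows: list[dict] = []

    def emit() -> None:
        snapshots.append((state.t_years, state.copy()))
        rows.append(_summary_row(state, audit))
        if cfg.checkpoint_path:
            save_checkpoint(state, cfg, cfg.checkpoint_path)

    if state.t == 0.0:
        emit()

    dt_morph = p.dt * p.phi
    total_s = duration_years * SECONDS_PER_YEAR
    snap_s = cfg.snapshot_every_years * SECONDS_PER_YEAR
    next_snap = (math.floor(state.t / snap_s) + 1) * snap_s
    n_step = 0
    while state.t < total_s - 0.5 * dt_morph:
        if use_fast:
            clamped, outflux = fused_step(state, p, grid, D0_arr,
                                          cfg.veg_dynamics, scratch)
            audit["clamped_volume"] += clamped
            audit["outflux"] = outflux
        else:
            step(state, p, grid, D0=D0, veg_dynamics=cfg.veg_dynamics,
                 advection=cfg.advection, audit=audit)
        n_step += 1
        if cfg.nan_check_every and n_step % cfg.nan_check_every == 0:
            state.check_finite()
        if cfg.log_every and n_step % cfg.log_every == 0:
            logger.info(
                "step %d  t=%.3f yr  mean h=%.4g m  mean S=%.4g m  "
                "clamped=%.4g m3  outflux=%.4g m3/s",
                n_step, state.t_years, state.h.mean(), state.S.mean(),
                audit["clamped_volume"], audit.get("outflux", float("nan")))
        if state.t >= next_snap - 0.5 * dt_morph:
            emit()
            next_snap += snap_s
    if not snapshots or snapshots[-1][0] < state.t_years:
        emit()

    return Trajectory(config=cfg, snapshots=snapshots,
                      summary=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _config_meta(cfg: RunConfig) -> str:
    meta = {
        "seed": cfg.seed,
        "grid": {"n_x": cfg.grid.n_x, "n_y": cfg.grid.n_y,
                 "dx": cfg.grid.dx, "dy": cfg.grid.dy},
        "params": cfg.params.as_dict(),
        "veg_dynamics": cfg.veg_dynamics,
        "advection": cfg.advection,
        "gradient": (None if cfg.gradient is None else
                     {"D0_min": cfg.gradient.D0_min,
                      "D0_max": cfg.gradient.D0_max,
                      "axis": cfg.gradient.axis}),
    }
    return json.dumps(meta)


def save_checkpoint(state: SimState, cfg: RunConfig, path: str | Path) -> None:
    """Write the full prognostic state plus parameters, seed and clock."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(t=np.array(state.t), h=state.h, u=state.u,
                  v=state.v, S=state.S, B=state.B,
                  meta=np.array(_config_meta(cfg)))
    if state.fric_cache is not None:
        arrays["fric_cache"] = state.fric_cache
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[SimState, RunConfig]:
    """Read a checkpoint back into a resumable (state, config) pair."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        state = SimState(t=float(z["t"]), h=z["h"], u=z["u"], v=z["v"],
                         S=z["S"], B=z["B"],
                         fric_cache=(z["fric_cache"]
                                     if "fric_cache" in z else None))
    cfg = RunConfig(
        grid=GridSpec(**meta["grid"]),
        params=ModelParams(**meta["params"]),
        seed=meta["seed"],
        veg_dynamics=meta["veg_dynamics"],
        advection=meta["advection"],
        gradient=(None if meta["gradient"] is None
                  else GradientSpec(**meta["gradient"])),
    )
    return state, cfg
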