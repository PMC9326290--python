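"""Explicit finite-difference simulation of postmortem body cooling.

The body and its environment are a labelled cubic grid (see
:mod:`thermopmi.geometry`).  Each time step exchanges thermal energy
between 6-connected neighbour cubes:

    T_i <- T_i + dt / (rho_i c_i dx^2) * sum_j k_ij (T_j - T_i)

with ``k_ij`` the harmonic mean ``2 k_i k_j / (k_i + k_j)`` of the two
cubes' conductivities — the standard conservative interface conductance
for discontinuous materials.  Clamped-ambient cubes are reset to the
(possibly time-varying) ambient temperature after every step, acting as an
infinite reservoir; air cubes within a configurable free-air shell of the
body evolve freely, modelling the warm boundary layer, while far-field
air is clamped.

No metabolic heat, radiation, or evaporative (humidity-dependent) terms
are modelled.  The scheme is explicit, so the time step must satisfy the
stability bound computed by :func:`stable_timestep`; updates are
Jacobi-style, always computed from the previous field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import InvalidConfigError, StabilityViolationError
from .geometry import AIR, LABEL_NAMES, LoggerSite, VoxelGrid
from .materials import MaterialTable

AmbientLike = float | Callable[[float], float]


def constant_ambient(value: float) -> Callable[[float], float]:
    return lambda t_h: value


def step_ambient(before: float, after: float, t_step_h: float) -> Callable[[float], float]:
    """Heaviside ambient change: ``before`` for t < t_step_h, ``after`` at and after."""
    return lambda t_h: after if t_h >= t_step_h else before


def periodic_ambient(mean: float, amplitude: float, period_h: float,
                     phase_h: float = 0.0) -> Callable[[float], float]:
    """Sinusoidal ambient cycle, e.g. a diurnal temperature swing."""
    return lambda t_h: mean + amplitude * math.sin(2 * math.pi * (t_h - phase_h) / period_h)


def _as_ambient_fn(ambient: AmbientLike) -> Callable[[float], float]:
    if callable(ambient):
        return ambient
    return constant_ambient(float(ambient))


@dataclass
class SimulationConfig:
    """Forward-run configuration.

    ``perimortem_temperature`` initialises every body cube;
    ``ambient_temperature`` (a number or a function of hours since death)
    initialises the environment and drives the clamped cubes.  With
    ``time_step="auto"`` the step is ``safety_factor`` times the explicit
    stability bound.
    """

    perimortem_temperature: float = 37.0
    ambient_temperature: AmbientLike = 20.0
    horizon_h: float = 48.0
    output_interval_min: float = 5.0
    time_step: float | str = "auto"
    safety_factor: float = 0.5
    free_air_shell_m: float = 0.05

    def __post_init__(self) -> None:
        if not self.horizon_h > 0:
            raise InvalidConfigError("horizon must be positive")
        if not self.output_interval_min > 0:
            raise InvalidConfigError("output interval must be positive")
        if not 0 < self.safety_factor <= 1:
            raise InvalidConfigError("safety factor must be in (0, 1]")

    def ambient_fn(self) -> Callable[[float], float]:
        return _as_ambient_fn(self.ambient_temperature)


@dataclass
class TemperatureField:
    """Per-cube temperatures (degC) at one instant (hours since death)."""

    temperatures: np.ndarray
    time_h: float


@dataclass
class CoolingCurve:
    """Temperature at one location as a function of hours since death."""

    location: str
    times_h: np.ndarray
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times_h.shape != self.temperatures.shape:
            raise InvalidConfigError("times and temperatures must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidConfigError("curve times must be strictly increasing")

    @property
    def span_h(self) -> float:
        return float(self.times_h[-1] - self.times_h[0])


class ThermalSystem:
    """Precomputed per-cube coefficients for the update kernel."""

    def __init__(self, grid: VoxelGrid, materials: MaterialTable,
                 free_air_shell_m: float = 0.05):
        self.grid = grid
        dx = grid.cube_size
        k = np.empty(grid.dims, dtype=np.float64)
        rc = np.empty(grid.dims, dtype=np.float64)
        for code, name in LABEL_NAMES.items():
            mask = grid.labels == code
            if not mask.any():
                continue
            props = materials[name]
            k[mask] = props.thermal_conductivity
            rc[mask] = props.volumetric_heat_capacity
        self.conductivity = k
        # harmonic-mean conductance across each interior face
        self.gx = 2 * k[:-1] * k[1:] / (k[:-1] + k[1:])
        self.gy = 2 * k[:, :-1] * k[:, 1:] / (k[:, :-1] + k[:, 1:])
        self.gz = 2 * k[:, :, :-1] * k[:, :, 1:] / (k[:, :, :-1] + k[:, :, 1:])
        self.coef = 1.0 / (rc * dx * dx)

        body = grid.body_mask
        far_air = np.zeros(grid.dims, dtype=bool)
        air = grid.labels == AIR
        if body.any() and air.any():
            dist = ndimage.distance_transform_edt(~body, sampling=dx)
            far_air = air & (dist > free_air_shell_m)
        self.clamped = grid.clamped | far_air
        self.free = ~self.clamped

    def neighbour_conductance_sum(self) -> np.ndarray:
        """sum_j k_ij over the in-grid 6-neighbours of every cube."""
        total = np.zeros(self.grid.dims, dtype=np.float64)
        total[:-1] += self.gx
        total[1:] += self.gx
        total[:, :-1] += self.gy
        total[:, 1:] += self.gy
        total[:, :, :-1] += self.gz
        total[:, :, 1:] += self.gz
        return total


def stable_timestep(grid: VoxelGrid, materials: MaterialTable,
                    safety_factor: float = 0.5,
                    free_air_shell_m: float = 0.05,
                    system: ThermalSystem | None = None) -> float:
    """Largest stable explicit step times ``safety_factor`` (seconds).

    The bound is ``min_i rho_i c_i dx^2 / sum_j k_ij`` over evolving
    (non-clamped) cubes, with harmonic-mean interface conductances.
    """
    sys_ = system or ThermalSystem(grid, materials, free_air_shell_m)
    total = sys_.neighbour_conductance_sum()
    free = sys_.free
    bound = 1.0 / (sys_.coef[free] * total[free])
    return float(safety_factor * bound.min())


@njit(cache=True)
def _advance(T, Tn, gx, gy, gz, coef, free, amb_vals, dt):  # pragma: no cover
    nx, ny, nz = T.shape
    for s in range(amb_vals.shape[0]):
        amb = amb_vals[s]
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not free[i, j, k]:
                        Tn[i, j, k] = amb
                        continue
                    t0 = T[i, j, k]
                    acc = 0.0
                    if i > 0:
                        acc += gx[i - 1, j, k] * (T[i - 1, j, k] - t0)
                    if i < nx - 1:
                        acc += gx[i, j, k] * (T[i + 1, j, k] - t0)
                    if j > 0:
                        acc += gy[i, j - 1, k] * (T[i, j - 1, k] - t0)
                    if j < ny - 1:
                        acc += gy[i, j, k] * (T[i, j + 1, k] - t0)
                    if k > 0:
                        acc += gz[i, j, k - 1] * (T[i, j, k - 1] - t0)
                    if k < nz - 1:
                        acc += gz[i, j, k] * (T[i, j, k + 1] - t0)
                    Tn[i, j, k] = t0 + dt * coef[i, j, k] * acc
        T, Tn = Tn, T
    return T


def step_temperature_field(fld: TemperatureField, grid: VoxelGrid,
                           materials: MaterialTable, dt: float,
                           ambient: AmbientLike = 20.0,
                           system: ThermalSystem | None = None) -> TemperatureField:
    """Advance the field by one explicit step of ``dt`` seconds.

    Raises :class:`StabilityViolationError` if ``dt`` exceeds the
    stability bound (safety factor 1).
    """
    sys_ = system or ThermalSystem(grid, materials)
    bound = stable_timestep(grid, materials, safety_factor=1.0, system=sys_)
    if dt > bound * (1 + 1e-12):
        raise StabilityViolationError(
            f"dt = {dt:.3g} s exceeds the explicit stability bound {bound:.3g} s")
    amb_fn = _as_ambient_fn(ambient)
    t_new_h = fld.time_h + dt / 3600.0
    amb_vals = np.array([amb_fn(t_new_h)], dtype=np.float64)
    T = np.array(fld.temperatures, dtype=np.float64)
    out = _advance(T, np.empty_like(T), sys_.gx, sys_.gy, sys_.gz,
                   sys_.coef, sys_.free, amb_vals, float(dt))
    return TemperatureField(temperatures=out.copy(), time_h=t_new_h)


def simulate_cooling(grid: VoxelGrid, materials: MaterialTable,
                     config: SimulationConfig,
                     sites: Sequence[LoggerSite],
                     return_final_field: bool = False):
    """Run a cooling simulation and record per-site skin-cooling curves.

    Body cubes start at the perimortem temperature, everything else at the
    ambient temperature at time zero.  Each site's cube temperature is
    recorded every output interval, including t = 0.

    Returns a list of :class:`CoolingCurve` (one per site, in order), or
    ``(curves, final_field)`` when ``return_final_field`` is set.
    """
    sys_ = ThermalSystem(grid, materials, config.free_air_shell_m)
    amb_fn = config.ambient_fn()

    interval_s = config.output_interval_min * 60.0
    n_out = round(config.horizon_h * 3600.0 / interval_s)
    if abs(n_out * interval_s - config.horizon_h * 3600.0) > 1e-6 * interval_s or n_out < 1:
        raise InvalidConfigError(
            "horizon must be a whole number of output intervals "
            f"(horizon {config.horizon_h} h, interval {config.output_interval_min} min)")

    bound = stable_timestep(grid, materials, safety_factor=1.0, system=sys_)
    if config.time_step == "auto":
        dt_target = bound * config.safety_factor
    else:
        dt_target = float(config.time_step)
        if dt_target > bound * (1 + 1e-12):
            raise StabilityViolationError(
                f"configured dt = {dt_target:.3g} s exceeds the stability bound {bound:.3g} s")
    n_sub = max(int(math.ceil(interval_s / dt_target)), 1)
    dt = interval_s / n_sub

    T = np.empty(grid.dims, dtype=np.float64)
    T[...] = amb_fn(0.0)
    T[grid.body_mask] = config.perimortem_temperature
    T[sys_.clamped] = amb_fn(0.0)

    site_idx = [s.grid_index for s in sites]
    records = np.empty((len(sites), n_out + 1), dtype=np.float64)
    for m, idx in enumerate(site_idx):
        records[m, 0] = T[idx]

    buf = np.empty_like(T)
    for out_step in range(1, n_out + 1):
        t0_s = (out_step - 1) * interval_s
        amb_vals = np.array([amb_fn((t0_s + (s + 1) * dt) / 3600.0)
                             for s in range(n_sub)], dtype=np.float64)
        result = _advance(T, buf, sys_.gx, sys_.gy, sys_.gz,
                          sys_.coef, sys_.free, amb_vals, dt)
        if result is not T:
            T, buf = result, T
        for m, idx in enumerate(site_idx):
            records[m, out_step] = T[idx]

    times_h = np.arange(n_out + 1) * (config.output_interval_min / 60.0)
    curves = [CoolingCurve(location=s.name, times_h=times_h.copy(),
                           temperatures=records[m].copy())
              for m, s in enumerate(sites)]
    if return_final_field:
        return curves, TemperatureField(temperatures=T.copy(), time_h=float(times_h[-1]))
    return curves
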