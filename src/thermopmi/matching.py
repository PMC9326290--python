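"""Co-registration of measured and simulated cooling curves.

The measured skin-temperature series starts at an unknown time since
death.  The cost of a candidate simulation is the minimal sum of squared
differences over a grid of candidate time offsets: for offset tau the
measured sample at relative time t_k is compared with the simulated curve
linearly interpolated at tau + t_k.  The offset of the winning evaluation
point is the candidate postmortem interval at the first measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .simulation import CoolingCurve

#: physiologically plausible skin-temperature range (degC); samples
#: outside it are flagged, not rejected
PLAUSIBLE_RANGE = (0.0, 45.0)


@dataclass
class MeasuredCurve:
    """A measured skin-temperature series at one logger location.

    ``relative_times_h`` are hours since the first sample and must start
    at zero; the clock time of the first sample, if known, is kept for
    reporting only.
    """

    location: str
    relative_times_h: np.ndarray
    temperatures: np.ndarray
    timestamp_of_first_sample: str | None = None

    def __post_init__(self) -> None:
        self.relative_times_h = np.asarray(self.relative_times_h, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.relative_times_h.shape != self.temperatures.shape:
            raise InvalidInputError("times and temperatures must have equal length")
        if self.relative_times_h.size < 5:
            raise InvalidInputError("a measured curve needs at least 5 samples")
        if abs(self.relative_times_h[0]) > 1e-12:
            raise InvalidInputError("relative times must start at 0")
        if np.any(np.diff(self.relative_times_h) <= 0):
            raise InvalidInputError("relative times must be strictly increasing")

    @property
    def span_h(self) -> float:
        return float(self.relative_times_h[-1])

    @property
    def physically_plausible(self) -> bool:
        lo, hi = PLAUSIBLE_RANGE
        return bool(np.all((self.temperatures >= lo) & (self.temperatures <= hi)))


@dataclass(frozen=True)
class AlignmentResult:
    """Best time alignment of a measured against a simulated curve."""

    cost: float
    best_offset_h: float
    offset_grid_resolution_h: float


def curve_cost(sim: CoolingCurve, meas: MeasuredCurve,
               offset_bounds_h: tuple[float, float] | None = None,
               offset_step_h: float | None = None) -> AlignmentResult:
    """Minimal sum of squared differences over a grid of time offsets.

    The simulated curve is linearly interpolated at ``tau + t_k`` for each
    candidate offset ``tau``; measured samples are never interpolated.
    Ties are broken toward the smaller offset.  Default offsets run from 0
    to ``horizon - span`` in steps of the simulation output interval.
    """
    if offset_step_h is None:
        offset_step_h = float(np.min(np.diff(sim.times_h)))
    if not offset_step_h > 0:
        raise InvalidConfigError("offset step must be positive")
    horizon = float(sim.times_h[-1])
    span = meas.span_h
    if span > horizon - float(sim.times_h[0]):
        raise InvalidConfigError(
            f"measurement span {span} h exceeds the simulation horizon {horizon} h")
    lo, hi = offset_bounds_h if offset_bounds_h is not None else (float(sim.times_h[0]), horizon - span)
    hi = min(hi, horizon - span)
    lo = max(lo, float(sim.times_h[0]))
    if hi < lo:
        raise InvalidConfigError("offset bounds leave no feasible offset")
    n_off = int(np.floor((hi - lo) / offset_step_h + 1e-9)) + 1
    offsets = lo + np.arange(n_off) * offset_step_h

    query = offsets[:, None] + meas.relative_times_h[None, :]
    sim_vals = np.interp(query, sim.times_h, sim.temperatures)
    costs = np.sum((sim_vals - meas.temperatures[None, :]) ** 2, axis=1)
    best = int(np.argmin(costs))  # argmin returns the first minimum: smaller tau wins ties
    return AlignmentResult(cost=float(costs[best]), best_offset_h=float(offsets[best]),
                           offset_grid_resolution_h=float(offset_step_h))


def joint_cost(sims: dict[str, CoolingCurve], curves: list[MeasuredCurve],
               offset_bounds_h: tuple[float, float] | None = None,
               offset_step_h: float | None = None) -> AlignmentResult:
    """Optional joint mode: one shared offset, costs summed over locations."""
    if not curves:
        raise InvalidInputError("no measured curves")
    total = None
    step = offset_step_h
    offsets = None
    for meas in curves:
        sim = sims[meas.location]
        if step is None:
            step = float(np.min(np.diff(sim.times_h)))
        horizon = float(sim.times_h[-1])
        span = meas.span_h
        if span > horizon:
            raise InvalidConfigError("measurement span exceeds the simulation horizon")
        lo, hi = offset_bounds_h if offset_bounds_h is not None else (0.0, horizon - span)
        hi = min(hi, horizon - span)
        n_off = int(np.floor((hi - lo) / step + 1e-9)) + 1
        cur_offsets = lo + np.arange(n_off) * step
        if offsets is None or cur_offsets.size < offsets.size:
            offsets = cur_offsets
        query = cur_offsets[:n_off, None] + meas.relative_times_h[None, :]
        vals = np.sum((np.interp(query, sim.times_h, sim.temperatures)
                       - meas.temperatures[None, :]) ** 2, axis=1)
        total = vals if total is None else total[: vals.size] + vals[: total.size]
    n = min(total.size, offsets.size)
    best = int(np.argmin(total[:n]))
    return AlignmentResult(cost=float(total[best]), best_offset_h=float(offsets[best]),
                           offset_grid_resolution_h=float(step))
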