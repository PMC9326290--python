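"""Surrogate-model-based search over (perimortem, ambient) temperature.

Each true cost evaluation is expensive (a full cooling simulation matched
against the measurement), so the search maintains a surrogate of the cost
function (SCF): a cubic radial-basis-function interpolant with a linear
polynomial tail, fitted over parameters scaled to the unit square and
exact at every evaluated point.  New evaluation points are chosen from a
fresh cloud of uniform random candidates by minimizing a merit measure

    f_merit(x, w) = w * S(x) + (1 - w) * D(x)

where S is the SCF scaled to [0, 1] over the candidates (0 at the
surrogate minimum — exploitation) and D is a scaled distance measure (0
at candidates farthest from evaluation history — exploration).  The
weight w cycles through (0.3, 0.5, 0.8, 0.95).  After the evaluation
budget is spent, the lowest-cost record wins; a global quadratic fit of
the evaluated costs flags the search as unsuccessful when the cost
surface is non-convex, since a minimum then cannot be guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .errors import (DegenerateDesignError, ExhaustedCandidatesError,
                     InsufficientDataError, InvalidConfigError)
from .matching import AlignmentResult

DEFAULT_BOUNDS = ((36.0, 38.0), (15.0, 25.0))
DEFAULT_WEIGHT_CYCLE = (0.3, 0.5, 0.8, 0.95)


@dataclass(frozen=True)
class ParameterPoint:
    """One (perimortem temperature, ambient temperature) combination, degC."""

    perimortem_temperature: float
    ambient_temperature: float

    def as_array(self) -> np.ndarray:
        return np.array([self.perimortem_temperature, self.ambient_temperature])


@dataclass
class EvaluationRecord:
    """A parameter point with its true (simulated) cost."""

    point: ParameterPoint
    cost: float
    alignment: AlignmentResult | None = None
    iteration: int = 0
    weight: float | None = None  # merit weight that selected this point; None for the initial design


@dataclass
class OptimizerConfig:
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS
    n_initial: int = 20
    n_total: int = 200
    weight_cycle: tuple[float, ...] = DEFAULT_WEIGHT_CYCLE
    candidates_per_iteration: int = 2000
    exclusion_radius: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_initial < self.n_total:
            raise InvalidConfigError("n_initial must be smaller than n_total")
        if any(not 0 <= w <= 1 for w in self.weight_cycle):
            raise InvalidConfigError("weights must lie in [0, 1]")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise InvalidConfigError("each bound must satisfy lower < upper")


class SurrogateState:
    """Evaluation history plus the current SCF interpolant."""

    def __init__(self, records: Sequence[EvaluationRecord],
                 bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS):
        self.records = list(records)
        self.bounds = np.asarray(bounds, dtype=float)
        self._interp: RBFInterpolator | None = None

    @property
    def points_scaled(self) -> np.ndarray:
        pts = np.array([r.point.as_array() for r in self.records])
        return scale_to_unit(pts, self.bounds)

    @property
    def costs(self) -> np.ndarray:
        return np.array([r.cost for r in self.records])

    def evaluate(self, candidates_scaled: np.ndarray) -> np.ndarray:
        """SCF values s(x) at scaled candidate points."""
        if self._interp is None:
            raise DegenerateDesignError("surrogate not fitted")
        return self._interp(np.atleast_2d(candidates_scaled))


def scale_to_unit(points: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    return (np.atleast_2d(points) - bounds[:, 0]) / (bounds[:, 1] - bounds[:, 0])


def unscale(points_scaled: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    bounds = np.asarray(bounds, dtype=float)
    return bounds[:, 0] + np.atleast_2d(points_scaled) * (bounds[:, 1] - bounds[:, 0])


def initial_design(config: OptimizerConfig, rng: np.random.Generator) -> list[ParameterPoint]:
    """n_initial uniform random points over the bounded rectangle.

    Points closer than the exclusion radius (in scaled space) to an
    already-drawn point are resampled, keeping the later interpolation
    system nonsingular.
    """
    bounds = np.asarray(config.bounds, dtype=float)
    chosen: list[np.ndarray] = []
    while len(chosen) < config.n_initial:
        x = rng.uniform(0.0, 1.0, size=bounds.shape[0])
        if chosen and np.min(np.linalg.norm(np.array(chosen) - x, axis=1)) <= config.exclusion_radius:
            continue
        chosen.append(x)
    pts = unscale(np.array(chosen), bounds)
    return [ParameterPoint(float(p), float(a)) for p, a in pts]


def fit_scf(records: Sequence[EvaluationRecord],
            bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS) -> SurrogateState:
    """Fit the SCF: cubic RBF + linear tail, exact at every record."""
    if len(records) < 4:
        raise DegenerateDesignError(
            f"need at least 4 evaluation records to fit the surrogate, got {len(records)}")
    state = SurrogateState(records, bounds)
    try:
        state._interp = RBFInterpolator(state.points_scaled, state.costs,
                                        kernel="cubic", degree=1)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(f"singular interpolation system: {exc}") from exc
    return state


def scaled_scf(state: SurrogateState, candidates_scaled: np.ndarray) -> np.ndarray:
    """S(x) = (s(x) - s_min) / (s_max - s_min) over the candidate set.

    S is 0 at candidates with minimal surrogate value; if all candidates
    share one value, S is identically 0.
    """
    s = state.evaluate(candidates_scaled)
    s_min, s_max = s.min(), s.max()
    if s_max == s_min:
        return np.zeros_like(s)
    return (s - s_min) / (s_max - s_min)


def scaled_distance(history_scaled: np.ndarray, candidates_scaled: np.ndarray) -> np.ndarray:
    """D(x) = (d_max - d(x)) / (d_max - d_min) over the candidate set.

    d(x) is the distance from candidate x to its nearest evaluated point
    (scaled space).  D is 0 at candidates farthest from history and 1 at
    candidates touching it; if all candidates are equidistant, D is 0.
    """
    history = np.atleast_2d(history_scaled)
    if history.shape[0] < 1:
        raise InsufficientDataError("need at least one evaluated point")
    d, _ = cKDTree(history).query(np.atleast_2d(candidates_scaled))
    d_min, d_max = d.min(), d.max()
    if d_max == d_min:
        return np.zeros_like(d)
    return (d_max - d) / (d_max - d_min)


def merit_measure(S: np.ndarray, D: np.ndarray, w: float) -> np.ndarray:
    """f_merit(x, w) = w * S(x) + (1 - w) * D(x), elementwise."""
    return w * np.asarray(S) + (1.0 - w) * np.asarray(D)


def propose_next_point(state: SurrogateState, config: OptimizerConfig,
                       iteration: int, rng: np.random.Generator) -> tuple[ParameterPoint, float]:
    """Select the next evaluation point from a fresh random candidate cloud.

    Candidates within the exclusion radius of any evaluated point are
    discarded; the survivor minimizing the merit measure wins (first in
    draw order on ties).  Returns the point and the weight used.
    """
    cand = rng.uniform(0.0, 1.0, size=(config.candidates_per_iteration, state.bounds.shape[0]))
    hist = state.points_scaled
    d, _ = cKDTree(hist).query(cand)
    keep = d > config.exclusion_radius
    if not keep.any():
        raise ExhaustedCandidatesError(
            "all candidates fell within the exclusion radius of evaluated points")
    cand = cand[keep]
    w = config.weight_cycle[iteration % len(config.weight_cycle)]
    S = scaled_scf(state, cand)
    D = scaled_distance(hist, cand)
    f = merit_measure(S, D, w)
    best = int(np.argmin(f))
    pt = unscale(cand[best], state.bounds)[0]
    return ParameterPoint(float(pt[0]), float(pt[1])), w


def convexity_check(records: Sequence[EvaluationRecord],
                    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS,
                    eig_tol: float = 1e-6) -> bool:
    """Is the evaluated cost surface consistent with a convex bowl?

    Fits s ~ a + b.x + x.H.x/2 by least squares in scaled space; returns
    True iff both eigenvalues of the symmetric Hessian are non-negative
    up to ``eig_tol`` times the largest magnitude.  A convex surface over
    the compact search rectangle always attains its minimum (possibly on
    the boundary, e.g. when the best-fit ambient temperature presses
    against a bound), so convexity of the fit is the whole test; saddles
    and multi-basin surfaces flag the search as unsuccessful.
    """
    if len(records) < 6:
        raise InsufficientDataError(
            f"convexity check needs at least 6 records, got {len(records)}")
    pts = scale_to_unit(np.array([r.point.as_array() for r in records]),
                        np.asarray(bounds, dtype=float))
    s = np.array([r.cost for r in records])
    x1, x2 = pts[:, 0], pts[:, 1]
    A = np.column_stack([np.ones_like(x1), x1, x2, x1 ** 2, x1 * x2, x2 ** 2])
    coef, *_ = np.linalg.lstsq(A, s, rcond=None)
    _, _, _, a11, a12, a22 = coef
    H = np.array([[2 * a11, a12], [a12, 2 * a22]])
    eigs = np.linalg.eigvalsh(H)
    max_mag = np.abs(eigs).max()
    if max_mag == 0:
        return False
    return bool(eigs.min() >= -eig_tol * max_mag)


@dataclass
class OptimizationResult:
    best: EvaluationRecord
    records: list[EvaluationRecord]
    estimated_pmi_h: float
    convexity_ok: bool
    success: bool
    seed: int = 0

    @property
    def best_cost(self) -> float:
        return self.best.cost


CostOracle = Callable[[ParameterPoint], tuple[float, AlignmentResult | None]]


def run_optimization(cost_oracle: CostOracle, config: OptimizerConfig,
                     rng: np.random.Generator | None = None,
                     progress: Callable[[EvaluationRecord], None] | None = None) -> OptimizationResult:
    """Full two-tier search: initial design, then merit-guided refinement.

    ``cost_oracle`` maps a :class:`ParameterPoint` to ``(cost, alignment)``
    where the alignment (may be None for analytic test costs) carries the
    time offset of the best match — the candidate PMI.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    design_rng, candidate_rng = rng.spawn(2)

    records: list[EvaluationRecord] = []
    for pt in initial_design(config, design_rng):
        cost, alignment = cost_oracle(pt)
        rec = EvaluationRecord(point=pt, cost=float(cost), alignment=alignment,
                               iteration=len(records), weight=None)
        records.append(rec)
        if progress:
            progress(rec)

    iteration = 0
    while len(records) < config.n_total:
        state = fit_scf(records, config.bounds)
        pt, w = propose_next_point(state, config, iteration, candidate_rng)
        cost, alignment = cost_oracle(pt)
        rec = EvaluationRecord(point=pt, cost=float(cost), alignment=alignment,
                               iteration=len(records), weight=w)
        records.append(rec)
        if progress:
            progress(rec)
        iteration += 1

    best = min(records, key=lambda r: r.cost)
    convex = convexity_check(records, config.bounds)
    pmi = best.alignment.best_offset_h if best.alignment is not None else float("nan")
    return OptimizationResult(best=best, records=records, estimated_pmi_h=pmi,
                              convexity_ok=convex, success=convex, seed=config.seed)


def trace_rows(result: OptimizationResult) -> list[dict]:
    """Optimizer trace as plain dicts (iteration, point, cost, offset, weight)."""
    rows = []
    for r in result.records:
        rows.append({
            "iteration": r.iteration,
            "perimortem_temperature_C": r.point.perimortem_temperature,
            "ambient_temperature_C": r.point.ambient_temperature,
            "cost_C2": r.cost,
            "best_offset_h": r.alignment.best_offset_h if r.alignment else float("nan"),
            "weight": r.weight if r.weight is not None else float("nan"),
        })
    return rows
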