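"""Surrogate search: SCF interpolation, merit measure, full optimization."""

import numpy as np
import pytest

from thermopmi.errors import (DegenerateDesignError, ExhaustedCandidatesError,
                              InsufficientDataError)
from thermopmi.optimizer import (DEFAULT_BOUNDS, EvaluationRecord,
                                 OptimizerConfig, ParameterPoint,
                                 convexity_check, fit_scf, initial_design,
                                 merit_measure, propose_next_point,
                                 run_optimization, scale_to_unit,
                                 scaled_distance, scaled_scf)


def record(p, a, cost, i=0):
    return EvaluationRecord(point=ParameterPoint(p, a), cost=cost, iteration=i)


def bowl(point, center=(36.87, 19.13), base=1.0):
    return base + (point.perimortem_temperature - center[0]) ** 2 \
        + (point.ambient_temperature - center[1]) ** 2


def two_basin(point):
    """Two unequal quadratic basins; global minimum near (37.5, 23)."""
    p, a = point.perimortem_temperature, point.ambient_temperature
    b1 = 2.0 + (p - 36.4) ** 2 + 0.15 * (a - 17.0) ** 2
    b2 = 1.2 + 1.5 * (p - 37.5) ** 2 + 0.1 * (a - 23.0) ** 2
    return min(b1, b2)


def grid_minimum(fn, n=201):
    P, A = np.meshgrid(np.linspace(36, 38, n), np.linspace(15, 25, n), indexing="ij")
    vals = np.array([[fn(ParameterPoint(P[i, j], A[i, j])) for j in range(n)]
                     for i in range(n)])
    return float(vals.min())


class TestInitialDesign:
    def test_deterministic_for_fixed_seed(self):
        cfg = OptimizerConfig(seed=5)
        d1 = initial_design(cfg, np.random.default_rng(5))
        d2 = initial_design(cfg, np.random.default_rng(5))
        assert d1 == d2

    def test_twenty_points_inside_bounds(self):
        cfg = OptimizerConfig()
        pts = initial_design(cfg, np.random.default_rng(0))
        assert len(pts) == 20
        for p in pts:
            assert 36.0 <= p.perimortem_temperature <= 38.0
            assert 15.0 <= p.ambient_temperature <= 25.0

    def test_pairwise_scaled_separation_exceeds_exclusion_radius(self):
        cfg = OptimizerConfig(seed=1)
        pts = initial_design(cfg, np.random.default_rng(1))
        scaled = scale_to_unit(np.array([p.as_array() for p in pts]),
                               np.asarray(cfg.bounds))
        d = np.linalg.norm(scaled[:, None] - scaled[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > cfg.exclusion_radius


class TestSCF:
    def test_interpolation_exact_at_records(self):
        rng = np.random.default_rng(0)
        recs = [record(rng.uniform(36, 38), rng.uniform(15, 25), rng.uniform(0, 50))
                for _ in range(15)]
        state = fit_scf(recs)
        values = state.evaluate(state.points_scaled)
        np.testing.assert_allclose(values, state.costs, rtol=1e-8)

    def test_constant_costs_reproduced_everywhere(self):
        recs = [record(36.2, 16.0, 7.5), record(37.9, 24.0, 7.5),
                record(36.5, 21.0, 7.5), record(37.2, 18.0, 7.5)]
        state = fit_scf(recs)
        probes = np.random.default_rng(1).uniform(0, 1, size=(50, 2))
        np.testing.assert_allclose(state.evaluate(probes), 7.5, rtol=1e-8)

    def test_three_records_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_scf([record(36.5, 16, 1), record(37, 20, 2), record(37.5, 24, 3)])


class TestScaledMeasures:
    @pytest.fixture
    def state(self):
        recs = [record(36.1, 15.5, 5), record(37.9, 24.5, 9),
                record(36.9, 20.0, 1), record(37.3, 17.0, 3)]
        return fit_scf(recs)

    def test_scaled_scf_hand_values(self):
        # direct formula on SCF values (2, 4, 10) -> (0, 0.25, 1)
        class Fake:
            def evaluate(self, c):
                return np.array([2.0, 4.0, 10.0])
        S = scaled_scf(Fake(), np.zeros((3, 2)))
        np.testing.assert_allclose(S, [0.0, 0.25, 1.0])

    def test_scaled_scf_degenerate_all_equal(self):
        class Fake:
            def evaluate(self, c):
                return np.full(4, 3.3)
        np.testing.assert_array_equal(scaled_scf(Fake(), np.zeros((4, 2))), np.zeros(4))

    def test_scaled_distance_hand_values(self):
        history = np.array([[0.0, 0.0]])
        cands = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])  # d = 0, 1, 2
        np.testing.assert_allclose(scaled_distance(history, cands), [1.0, 0.5, 0.0])

    def test_coincident_candidate_scores_one_and_farthest_zero(self):
        history = np.array([[0.5, 0.5]])
        cands = np.array([[0.5, 0.5], [0.0, 0.0]])
        D = scaled_distance(history, cands)
        assert D[0] == 1.0 and D[1] == 0.0

    def test_in_unit_interval_on_random_iterations(self, state):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cands = rng.uniform(0, 1, size=(200, 2))
            S = scaled_scf(state, cands)
            D = scaled_distance(state.points_scaled, cands)
            assert np.all((S >= 0) & (S <= 1))
            assert np.all((D >= 0) & (D <= 1))


class TestMeritMeasure:
    def test_endpoints_and_hand_value(self):
        S, D = np.array([0.5]), np.array([0.2])
        assert merit_measure(S, D, 1.0)[0] == 0.5
        assert merit_measure(S, D, 0.0)[0] == 0.2
        assert merit_measure(S, D, 0.3)[0] == pytest.approx(0.29)


class TestProposeNextPoint:
    def test_weight_cycle_repeats_every_four(self):
        cfg = OptimizerConfig(seed=0)
        recs = [record(36.2, 16, 5), record(37.8, 24, 9),
                record(36.9, 20, 1), record(37.3, 17, 3)]
        state = fit_scf(recs)
        rng = np.random.default_rng(0)
        weights = [propose_next_point(state, cfg, i, rng)[1] for i in range(5)]
        assert weights == [0.3, 0.5, 0.8, 0.95, 0.3]

    def test_never_returns_point_inside_exclusion_radius(self):
        cfg = OptimizerConfig(seed=0, exclusion_radius=0.05, candidates_per_iteration=500)
        recs = [record(36.2, 16, 5), record(37.8, 24, 9),
                record(36.9, 20, 1), record(37.3, 17, 3)]
        state = fit_scf(recs)
        rng = np.random.default_rng(2)
        hist = state.points_scaled
        for i in range(20):
            pt, _ = propose_next_point(state, cfg, i, rng)
            x = scale_to_unit(pt.as_array(), state.bounds)[0]
            assert np.linalg.norm(hist - x, axis=1).min() > cfg.exclusion_radius

    def test_exhausted_candidates_error(self):
        # exclusion radius larger than the scaled domain diagonal
        cfg = OptimizerConfig(seed=0, exclusion_radius=2.0, candidates_per_iteration=50)
        recs = [record(36.2, 16, 5), record(37.8, 24, 9),
                record(36.9, 20, 1), record(37.3, 17, 3)]
        state = fit_scf(recs)
        with pytest.raises(ExhaustedCandidatesError):
            propose_next_point(state, cfg, 0, np.random.default_rng(0))


class TestConvexityCheck:
    def test_convex_bowl_detected(self):
        rng = np.random.default_rng(0)
        recs = [record(p, a, (scale_to_unit([p, a], np.asarray(DEFAULT_BOUNDS))[0][0] - 0.5) ** 2
                       + (scale_to_unit([p, a], np.asarray(DEFAULT_BOUNDS))[0][1] - 0.5) ** 2)
                for p, a in zip(rng.uniform(36, 38, 30), rng.uniform(15, 25, 30))]
        assert convexity_check(recs) is True

    def test_saddle_rejected(self):
        rng = np.random.default_rng(1)
        recs = []
        for p, a in zip(rng.uniform(36, 38, 30), rng.uniform(15, 25, 30)):
            x = scale_to_unit([p, a], np.asarray(DEFAULT_BOUNDS))[0]
            recs.append(record(p, a, x[0] ** 2 - x[1] ** 2))
        assert convexity_check(recs) is False

    def test_five_records_insufficient(self):
        recs = [record(36 + 0.3 * i, 15 + i, float(i)) for i in range(5)]
        with pytest.raises(InsufficientDataError):
            convexity_check(recs)


class TestRunOptimization:
    def test_default_protocol_produces_200_records(self):
        cfg = OptimizerConfig(seed=11)
        res = run_optimization(lambda p: (bowl(p), None), cfg)
        assert len(res.records) == 200
        initial = res.records[:20]
        assert all(r.weight is None for r in initial)
        assert res.best.cost == min(r.cost for r in res.records)
        assert res.best.cost <= min(r.cost for r in initial)

    def test_bowl_minimum_found_within_one_percent_of_grid(self):
        gmin = grid_minimum(lambda p: bowl(p))
        dists = []
        for seed in range(10):
            res = run_optimization(lambda p: (bowl(p), None),
                                   OptimizerConfig(seed=seed))
            assert res.best.cost <= gmin * 1.01, seed
            dists.append(np.linalg.norm(res.best.point.as_array() - [36.87, 19.13]))
        assert np.mean(dists) <= 0.05

    def test_two_basin_minimum_found_within_one_percent_of_grid(self):
        gmin = grid_minimum(two_basin)
        for seed in range(10):
            res = run_optimization(lambda p: (two_basin(p), None),
                                   OptimizerConfig(seed=seed))
            assert res.best.cost <= gmin * 1.01, seed

    def test_beats_15x15_exhaustive_grid_on_both_test_costs(self):
        for fn in (lambda p: bowl(p), two_basin):
            P, A = np.meshgrid(np.linspace(36, 38, 15), np.linspace(15, 25, 15),
                               indexing="ij")
            grid_best = min(fn(ParameterPoint(p, a))
                            for p, a in zip(P.ravel(), A.ravel()))
            for seed in range(10):
                res = run_optimization(lambda p: (fn(p), None),
                                       OptimizerConfig(seed=seed))
                assert res.best.cost <= grid_best

    def test_scf_exact_after_every_refit(self):
        cfg = OptimizerConfig(seed=3, n_initial=6, n_total=20)
        res = run_optimization(lambda p: (bowl(p), None), cfg)
        state = fit_scf(res.records, cfg.bounds)
        np.testing.assert_allclose(state.evaluate(state.points_scaled),
                                   state.costs, rtol=1e-8)

    def test_merit_evaluations_are_cheap_relative_to_simulation(self, materials,
                                                                coarse_phantom):
        """The surrogate exists because one forward simulation dwarfs the
        per-iteration surrogate work (fit + thousands of merit values)."""
        import time
        from thermopmi.geometry import locate_logger_voxel
        from thermopmi.simulation import SimulationConfig, simulate_cooling
        cloud, grid = coarse_phantom
        site = locate_logger_voxel(grid, cloud.logger_sites["chest"], name="chest")
        cfg = SimulationConfig(horizon_h=10.0)
        simulate_cooling(grid, materials, cfg, [site])  # warm the JIT
        t0 = time.perf_counter()
        simulate_cooling(grid, materials, cfg, [site])
        sim_time = time.perf_counter() - t0

        rng = np.random.default_rng(0)
        recs = [record(rng.uniform(36, 38), rng.uniform(15, 25), rng.uniform(0, 50))
                for _ in range(200)]
        ocfg = OptimizerConfig(seed=0)
        t0 = time.perf_counter()
        state = fit_scf(recs)
        propose_next_point(state, ocfg, 0, rng)
        surrogate_time = time.perf_counter() - t0
        assert surrogate_time < sim_time
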