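"""Unit tests for the four-state kinetic model."""

import numpy as np
import pytest

from rckinetics import (
    DARK_ADAPTED,
    LIGHT_DRIVEN,
    RATE_NAMES,
    OccupancyState,
    RateSet,
    RateValidationError,
    Trajectory,
    build_generator,
    decrements,
    eigensolution,
    protocol_turning_points,
    simulate_protocol,
    solve_occupancies,
    steady_state,
    turning_points,
)
from rckinetics.model import _integrate

from conftest import random_rateset


class TestRateSet:
    def test_field_order_matches_table_columns(self):
        assert RATE_NAMES == ("k12", "k21", "k23", "k32", "k34", "k43",
                              "k13", "k31", "k24", "k42", "k14", "k41")

    def test_negative_rate_rejected(self):
        with pytest.raises(RateValidationError):
            RateSet(k12=-1.0)

    def test_non_finite_rate_rejected(self):
        with pytest.raises(RateValidationError):
            RateSet(k21=np.nan)

    def test_dict_round_trip(self):
        rs = RateSet(k12=1.5, k41=0.25)
        assert RateSet.from_dict(rs.to_dict()) == rs

    def test_json_round_trip(self, tmp_path):
        rs = RateSet(k12=0.123456789012345, k34=2.0)
        path = tmp_path / "rates.json"
        rs.to_json(path, process="oxidation", intensity_mw_cm2=0.2)
        assert RateSet.from_json(path) == rs

    def test_is_dark(self):
        assert RateSet(k21=1.0).is_dark
        assert not RateSet(k12=1.0).is_dark

    def test_replace_returns_new_instance(self):
        rs = RateSet(k12=1.0)
        rs2 = rs.replace(k21=2.0)
        assert rs.k21 == 0.0 and rs2.k21 == 2.0 and rs2.k12 == 1.0


class TestOccupancyState:
    def test_sum_constraint(self):
        with pytest.raises(ValueError):
            OccupancyState(0.5, 0.5, 0.5, 0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            OccupancyState(1.5, -0.5, 0.0, 0.0)

    def test_from_array_renormalizes_roundoff(self):
        x = OccupancyState.from_array([1.0 + 1e-14, -1e-16, 0.0, 0.0])
        assert abs(sum(x.as_array()) - 1.0) < 1e-15


class TestGenerator:
    def test_columns_sum_to_zero(self, rng):
        for _ in range(20):
            Q = build_generator(random_rateset(rng))
            assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)

    def test_off_diagonals_nonnegative(self, rng):
        Q = build_generator(random_rateset(rng))
        off = Q[~np.eye(4, dtype=bool)]
        assert np.all(off >= 0)

    def test_transpose_convention(self):
        # dx2/dt gains k12*x1: Q[1, 0] = k12
        Q = build_generator(RateSet(k12=3.0))
        assert Q[1, 0] == 3.0 and Q[0, 0] == -3.0


class TestDecrements:
    def test_two_state_subsystem(self):
        d = decrements(RateSet(k12=1.0, k21=2.0))
        assert np.allclose(np.sort(d)[::-1], [3.0, 0.0, 0.0], atol=1e-12)

    def test_characteristic_polynomial_oracle(self, ox_2):
        """Eigen-decrements agree with companion-matrix roots to 1e-9."""
        Q = build_generator(ox_2)
        coeffs = np.poly(Q)                      # characteristic polynomial
        roots = np.roots(coeffs)
        ref = -roots[np.argsort(np.abs(roots))][1:]   # drop conservation root
        d = decrements(ox_2)
        assert np.allclose(np.sort(d.real), np.sort(ref.real), atol=1e-9)

    def test_exactly_three_returned(self, rng):
        for _ in range(10):
            assert decrements(random_rateset(rng)).shape == (3,)

    def test_nonnegative_real_parts(self, rng):
        for _ in range(20):
            d = decrements(random_rateset(rng))
            assert np.all(np.real(d) >= -1e-12)


class TestEigenSolution:
    def test_reconstruction_matches_solver(self, ox_02):
        t = np.linspace(0.0, 60.0, 301)
        sol = eigensolution(ox_02, DARK_ADAPTED)
        traj = solve_occupancies(ox_02, DARK_ADAPTED, t)
        assert np.max(np.abs(sol.evaluate(t) - traj.states)) < 1e-10

    def test_long_time_limit_is_steady(self, ox_02):
        sol = eigensolution(ox_02, DARK_ADAPTED)
        x_inf = sol.evaluate(np.array([1e6]))[0]
        assert np.max(np.abs(x_inf - sol.steady)) < 1e-10

    def test_derivative_matches_generator(self, ox_02):
        sol = eigensolution(ox_02, DARK_ADAPTED)
        Q = build_generator(ox_02)
        x = sol.evaluate(np.array([5.0]))[0]
        assert np.allclose(sol.derivative(5.0), Q @ x, atol=1e-10)


class TestSolveOccupancies:
    def test_two_state_closed_form(self):
        """x1(t) = (k21 + k12 e^{-(k12+k21) t}) / (k12 + k21)."""
        k12, k21 = 1.3, 0.7
        t = np.linspace(0.0, 10.0, 501)
        traj = solve_occupancies(RateSet(k12=k12, k21=k21), DARK_ADAPTED, t)
        s = k12 + k21
        exact = (k21 + k12 * np.exp(-s * t)) / s
        assert np.max(np.abs(traj.x1 - exact)) < 1e-12

    def test_conservation_everywhere(self, rng):
        t = np.linspace(0.0, 30.0, 301)
        for _ in range(10):
            traj = solve_occupancies(random_rateset(rng), DARK_ADAPTED, t)
            assert traj.conservation_error() <= 1e-12

    def test_nonnegative_occupancies(self, rng):
        t = np.linspace(0.0, 30.0, 301)
        for _ in range(10):
            traj = solve_occupancies(random_rateset(rng), DARK_ADAPTED, t)
            assert np.all(traj.states >= 0)

    def test_shifted_time_grid(self, ox_02):
        t = np.linspace(0.0, 10.0, 101)
        a = solve_occupancies(ox_02, DARK_ADAPTED, t).states
        b = solve_occupancies(ox_02, DARK_ADAPTED, t + 5.0).states
        assert np.allclose(a, b, atol=1e-12)

    def test_defective_generator_falls_back(self):
        """k12 = k23 = 1 gives a Jordan block; x2(t) = t e^{-t} exactly."""
        t = np.linspace(0.0, 10.0, 201)
        traj = solve_occupancies(RateSet(k12=1.0, k23=1.0), DARK_ADAPTED, t)
        assert np.max(np.abs(traj.occupancy(2) - t * np.exp(-t))) < 1e-8
        assert traj.conservation_error() <= 1e-12

    def test_invalid_grid_rejected(self, ox_02):
        with pytest.raises(ValueError):
            solve_occupancies(ox_02, DARK_ADAPTED, np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            solve_occupancies(ox_02, DARK_ADAPTED, np.array([]))

    def test_matches_numerical_integration(self, ox_02):
        t = np.linspace(0.0, 60.0, 201)
        a = solve_occupancies(ox_02, DARK_ADAPTED, t).states
        b = _integrate(build_generator(ox_02), DARK_ADAPTED.as_array(), t)
        assert np.max(np.abs(a - b)) < 1e-8


class TestSteadyState:
    def test_irreducible_network_null_vector(self, ox_02):
        x = steady_state(ox_02)
        Q = build_generator(ox_02)
        assert np.max(np.abs(Q @ x.as_array())) < 1e-12

    def test_dark_network_absorbs_into_state_1(self, red_02):
        x = steady_state(red_02)
        assert abs(x.x1 - 1.0) < 1e-12

    def test_multiple_closed_classes_rejected(self):
        with pytest.raises(ValueError, match="closed"):
            steady_state(RateSet())     # four isolated states


class TestProtocol:
    def test_non_dark_reduction_rejected(self, ox_02):
        with pytest.raises(RateValidationError, match="dark"):
            simulate_protocol(ox_02, ox_02, DARK_ADAPTED, 10.0, 20.0)

    def test_handoff_continuity(self, ox_02, red_02):
        traj = simulate_protocol(ox_02, red_02, DARK_ADAPTED, 30.0, 60.0, dt=0.01)
        i = int(np.argmax(traj.phases == "off"))
        jump = np.abs(traj.states[i] - traj.states[i - 1])
        assert np.max(jump) < 5e-3     # one dt step, not a discontinuity

    def test_phase_labels(self, ox_02, red_02):
        traj = simulate_protocol(ox_02, red_02, DARK_ADAPTED, 30.0, 60.0, dt=0.1)
        on = traj.phases == "on"
        assert traj.times[on].max() <= 30.0 + 1e-9
        assert traj.times[~on].min() > 30.0

    def test_bad_switch_times_rejected(self, ox_02, red_02):
        with pytest.raises(ValueError):
            simulate_protocol(ox_02, red_02, DARK_ADAPTED, 60.0, 30.0)


class TestTurningPoints:
    def test_multi_phase_rejected(self, ox_02, red_02):
        traj = simulate_protocol(ox_02, red_02, DARK_ADAPTED, 30.0, 60.0, dt=0.1)
        with pytest.raises(ValueError, match="single-phase"):
            turning_points(traj, 2, ox_02)

    def test_monotone_trace_has_none(self):
        rs = RateSet(k12=1.0, k21=2.0)
        t = np.linspace(0.0, 10.0, 101)
        traj = solve_occupancies(rs, DARK_ADAPTED, t)
        assert turning_points(traj, 1, rs) == []

    def test_x2_maximum_found(self, ox_02):
        t = np.arange(0.0, 90.005, 0.01)
        traj = solve_occupancies(ox_02, DARK_ADAPTED, t)
        tps = [tp for tp in turning_points(traj, 2, ox_02) if tp[1] == "max"]
        assert len(tps) == 1
        t_star = tps[0][0]
        # extremum: the sampled x2 peaks at the same grid location
        i_grid = int(np.argmax(traj.occupancy(2)))
        assert abs(t_star - t[i_grid]) < 0.05

    def test_off_phase_times_relative_to_light_off(self, ox_02, red_02):
        traj = simulate_protocol(ox_02, red_02, DARK_ADAPTED, 90.0, 300.0, dt=0.01)
        tp = protocol_turning_points(traj, 4, ox_02, red_02)
        assert all(0.0 <= t <= 210.0 for t, _ in tp["off"])


class TestTrajectoryIO:
    def test_csv_round_trip_lossless(self, tmp_path, ox_02, red_02):
        traj = simulate_protocol(ox_02, red_02, DARK_ADAPTED, 5.0, 10.0, dt=0.1)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.allclose(back.states, traj.states, rtol=1e-14, atol=1e-16)
        assert np.array_equal(back.phases, traj.phases)
        with open(path) as fh:
            assert fh.readline().strip() == "time_s,x1,x2,x3,x4,phase"

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.zeros((3, 4)),
                       np.array(["on"] * 2, dtype=object))
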