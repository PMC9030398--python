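"""Redundancy-resolution strategies against their analytic and grid oracles."""

import numpy as np
import pytest

from wristopt import (
    GeneratorConfig,
    InfeasibleInstanceError,
    InvalidParameterError,
    JointInstance,
    brute_force_oracle,
    cb_interior_closed_form,
    cb_objective,
    equilibrium_residual,
    generate_instances,
    max_stress_objective,
    minimax_equal_stress,
    pcsa_shares,
    solve_cb,
    solve_minimax,
    solve_weighted_sum,
)

# Exact worked-example solution of the weighted-sum substitution in N*cm
# units: denominator 0.22 + 0.42 + 0.20 = 0.84 cm, F = 1000/0.84.
WS_TOTAL_2DP = 1000.0 / 0.84
# Exact-fraction total: M / sum(d_i * PCSA_i / 1300) = 13e6 / 10870 N.
WS_TOTAL_EXACT = 13_000_000 / 10870


def random_instances(count, seed, min_arm=0.0):
    config = GeneratorConfig(muscle_count=3, seed=seed, arm_bounds=(min_arm, 30.0))
    return list(generate_instances(config, count))


class TestWeightedSum:
    def test_two_decimal_substitution_total(self, worked_instance):
        sol = solve_weighted_sum(worked_instance, rounding="two_decimal")
        assert sol.objective_value == pytest.approx(WS_TOTAL_2DP)
        assert round(sol.objective_value, 2) == 1190.48

    def test_two_decimal_per_muscle_split(self, worked_instance):
        sol = solve_weighted_sum(worked_instance, rounding="two_decimal")
        assert sol.forces == pytest.approx(
            [0.37 * WS_TOTAL_2DP, 0.35 * WS_TOTAL_2DP, 0.28 * WS_TOTAL_2DP]
        )
        assert np.round(sol.forces, 2).tolist() == [440.48, 416.67, 333.33]

    def test_two_decimal_mode_reports_rounding_residual(self, worked_instance):
        sol = solve_weighted_sum(worked_instance, rounding="two_decimal")
        assert sol.residual != 0.0  # rounding error is carried, not hidden
        assert "rounding" in sol.diagnostics

    def test_exact_mode_total_and_equilibrium(self, worked_instance):
        sol = solve_weighted_sum(worked_instance)
        assert sol.total_force == pytest.approx(WS_TOTAL_EXACT, rel=1e-12)
        assert abs(sol.residual) < 1e-8 * worked_instance.moment

    def test_single_muscle_reduces_to_moment_over_arm(self):
        inst = JointInstance(names=("a",), pcsa=(321.0,), arms=(8.0,), moment=4000.0)
        sol = solve_weighted_sum(inst)
        assert sol.forces[0] == pytest.approx(4000.0 / 8.0)

    def test_pcsa_shares_of_worked_instance(self, worked_instance):
        assert pcsa_shares(worked_instance) == pytest.approx(
            [100 * 480 / 1300, 100 * 450 / 1300, 100 * 370 / 1300]
        )

    def test_unknown_rounding_mode_rejected(self, worked_instance):
        with pytest.raises(InvalidParameterError):
            solve_weighted_sum(worked_instance, rounding="3dp")


class TestStressCostFamily:
    def test_n1_concentrates_on_best_leverage_vertex(self, worked_instance):
        sol = solve_cb(worked_instance, 1)
        # ECRB maximizes d_i * PCSA_i, so the LP loads it alone: M / d = 833.33 N
        assert sol.forces == pytest.approx([0.0, 10000.0 / 12.0, 0.0], abs=1e-6)

    def test_n2_quadratic_solution(self, worked_instance):
        sol = solve_cb(worked_instance, 2)
        assert np.round(sol.forces, 2).tolist() == [313.03, 550.24, 216.99]

    def test_n3_nonlinear_solution(self, worked_instance):
        sol = solve_cb(worked_instance, 3)
        assert np.round(sol.forces, 2).tolist() == [377.05, 484.03, 275.62]

    def test_n2_matches_closed_form_to_1e9(self):
        for inst in random_instances(25, seed=7, min_arm=0.5):
            closed = cb_interior_closed_form(inst, 2)
            solved = solve_cb(inst, 2).forces
            assert np.max(np.abs(solved - closed) / np.maximum(closed, 1e-9)) < 1e-9

    def test_closed_form_reproduces_worked_n2(self, worked_instance):
        closed = cb_interior_closed_form(worked_instance, 2)
        # stationarity: forces proportional to d_i * PCSA_i^2
        c = np.array([6 * 480**2, 12 * 450**2, 7 * 370**2], dtype=float)
        expected = 10000.0 * c / (np.array([6.0, 12.0, 7.0]) @ c)
        assert closed == pytest.approx(expected, rel=1e-14)
        assert np.round(closed, 2).tolist() == [313.03, 550.24, 216.99]

    def test_closed_form_symmetry_two_identical_muscles(self):
        inst = JointInstance(
            names=("a", "b"), pcsa=(200.0, 200.0), arms=(5.0, 5.0), moment=1000.0
        )
        assert cb_interior_closed_form(inst, 2) == pytest.approx(
            [1000.0 / 10.0, 1000.0 / 10.0]
        )

    def test_max_stress_non_increasing_in_exponent(self):
        exponents = (1, 2, 3, 5, 10, 50)
        for inst in random_instances(10, seed=11, min_arm=0.5):
            stresses = [solve_cb(inst, n).max_stress for n in exponents]
            for lo, hi in zip(stresses[1:], stresses[:-1]):
                assert lo <= hi * (1 + 1e-9)

    def test_large_exponent_approaches_minimax(self, worked_instance):
        sigma_star = minimax_equal_stress(worked_instance)
        assert solve_cb(worked_instance, 50).max_stress == pytest.approx(
            sigma_star, rel=0.01
        )

    def test_lp_vertex_matches_enumeration(self):
        for inst in random_instances(50, seed=3, min_arm=0.5):
            arms = inst.arm_array()
            pcsa = inst.pcsa_array()
            # one vertex per muscle: all load on it; cost M / (d_i PCSA_i)
            best = int(np.argmax(arms * pcsa))
            sol = solve_cb(inst, 1)
            expected = np.zeros(inst.m)
            expected[best] = inst.moment / arms[best]
            assert sol.forces == pytest.approx(expected, abs=1e-6 * inst.moment)

    def test_lp_tie_returns_first_index_vertex(self):
        inst = JointInstance(
            names=("a", "b"), pcsa=(100.0, 50.0), arms=(5.0, 10.0), moment=1000.0
        )  # d*PCSA = 500 both
        sol = solve_cb(inst, 1)
        assert sol.forces == pytest.approx([1000.0 / 5.0, 0.0])
        assert "non-unique" in sol.diagnostics

    def test_zero_arm_muscle_gets_zero_force(self):
        inst = JointInstance(
            names=("a", "b", "c"),
            pcsa=(480.0, 450.0, 370.0),
            arms=(6.0, 12.0, 0.0),
            moment=10000.0,
        )
        sol = solve_cb(inst, 2)
        assert sol.forces[2] == 0.0
        assert abs(sol.residual) < 1e-6 * inst.moment

    def test_exponent_below_one_rejected(self, worked_instance):
        with pytest.raises(InvalidParameterError):
            solve_cb(worked_instance, 0.5)

    def test_closed_form_preconditions(self, worked_instance):
        with pytest.raises(InvalidParameterError):
            cb_interior_closed_form(worked_instance, 1.0)
        inst = JointInstance(
            names=("a", "b"), pcsa=(10.0, 10.0), arms=(5.0, 0.0), moment=10.0
        )
        with pytest.raises(InvalidParameterError):
            cb_interior_closed_form(inst, 2)


class TestMinimax:
    def test_worked_instance_forces(self, worked_instance):
        sol = solve_minimax(worked_instance)
        assert np.round(sol.forces, 2).tolist() == [441.58, 413.98, 340.39]

    def test_equalizes_stresses_at_sigma_star(self, worked_instance):
        sol = solve_minimax(worked_instance)
        sigma_star = 10000.0 / (6 * 480 + 12 * 450 + 7 * 370)
        assert sigma_star == pytest.approx(0.920, abs=5e-4)
        assert sol.stresses == pytest.approx([sigma_star] * 3, rel=1e-9)

    def test_equal_muscles_split_evenly(self):
        inst = JointInstance(
            names=("a", "b", "c", "d"),
            pcsa=(100.0,) * 4,
            arms=(5.0,) * 4,
            moment=2000.0,
        )
        sol = solve_minimax(inst)
        assert sol.forces == pytest.approx([2000.0 / (4 * 5.0)] * 4)


class TestCrossMethodProperties:
    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_homogeneity_in_the_moment(self, worked_instance, k):
        import dataclasses

        scaled = dataclasses.replace(
            worked_instance, moment=k * worked_instance.moment
        )
        for solve in (
            lambda i: solve_weighted_sum(i),
            lambda i: solve_cb(i, 1),
            lambda i: solve_cb(i, 2),
            lambda i: solve_cb(i, 3),
            solve_minimax,
        ):
            base = solve(worked_instance).forces
            assert solve(scaled).forces == pytest.approx(k * base, rel=1e-8)

    def test_all_solvers_satisfy_equilibrium_and_nonnegativity(self):
        for inst in random_instances(20, seed=5):
            for sol in (
                solve_weighted_sum(inst),
                solve_cb(inst, 1),
                solve_cb(inst, 2),
                solve_cb(inst, 3),
                solve_minimax(inst),
            ):
                assert np.all(sol.forces >= 0)
                assert abs(sol.residual) <= 1e-6 * max(1.0, inst.moment)
                assert sol.stresses == pytest.approx(
                    sol.forces / inst.pcsa_array(), rel=1e-12
                )

    def test_single_muscle_every_method_returns_moment_over_arm(self):
        inst = JointInstance(names=("a",), pcsa=(250.0,), arms=(4.0,), moment=1000.0)
        expected = [1000.0 / 4.0]
        for sol in (
            solve_weighted_sum(inst),
            solve_cb(inst, 1),
            solve_cb(inst, 2),
            solve_cb(inst, 3),
            solve_minimax(inst),
        ):
            assert sol.forces == pytest.approx(expected, rel=1e-9)


class TestBruteForceOracle:
    def test_worked_instance_quadratic_objective(self, worked_instance):
        ref = brute_force_oracle(
            worked_instance, cb_objective(worked_instance.pcsa, 2), grid_points=101
        )
        closed = cb_interior_closed_form(worked_instance, 2)
        assert np.max(np.abs(ref - closed)) < 0.01 * closed.sum()

    def test_worked_instance_max_stress_objective(self, worked_instance):
        ref = brute_force_oracle(
            worked_instance, max_stress_objective(worked_instance.pcsa)
        )
        mm = solve_minimax(worked_instance).forces
        assert np.max(np.abs(ref - mm)) < 0.01 * mm.sum()

    def test_single_muscle_is_exact_for_any_objective(self):
        inst = JointInstance(names=("a",), pcsa=(100.0,), arms=(5.0,), moment=1000.0)
        ref = brute_force_oracle(inst, cb_objective(inst.pcsa, 3))
        assert ref == pytest.approx([1000.0 / 5.0])

    def test_agreement_on_random_instances(self):
        for inst in random_instances(20, seed=17):
            for sol, objective in (
                (solve_cb(inst, 2), cb_objective(inst.pcsa, 2)),
                (solve_minimax(inst), max_stress_objective(inst.pcsa)),
            ):
                ref = brute_force_oracle(inst, objective)
                assert np.max(np.abs(sol.forces - ref)) <= 0.01 * sol.total_force

    def test_desk_scale_only(self):
        inst = JointInstance(
            names=tuple("abcde"),
            pcsa=(100.0,) * 5,
            arms=(5.0,) * 5,
            moment=1000.0,
        )
        with pytest.raises(InvalidParameterError):
            brute_force_oracle(inst, cb_objective(inst.pcsa, 2))
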