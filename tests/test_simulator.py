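import numpy as np
import pytest
from scipy.integrate import solve_ivp

from iadtmodels import (
    SimulationError, TreatmentSchedule, closed_form_androgen,
    closed_form_androgen_derivative, default_params, get_model, simulate,
)

CA0, DELTA_A = 2.0, 0.05


def i08a_params(c_A0=CA0, delta_cA=DELTA_A):
    md = get_model("I08A")
    d = md.pdict(default_params("I08A"))
    d["c_A0"], d["delta_cA"] = c_A0, delta_cA
    return md.pvector(d)


class TestClosedFormAndrogen:
    def test_value_at_minus_one_is_homeostatic(self):
        assert closed_form_androgen(CA0, DELTA_A, -1.0) == pytest.approx(CA0)

    def test_off_treatment_recovery_limit(self):
        t = 40.0 / DELTA_A
        assert closed_form_androgen(CA0, DELTA_A, t) == pytest.approx(
            CA0, abs=1e-12)

    def test_continuous_at_switch(self):
        left = closed_form_androgen(CA0, DELTA_A, -1e-9)
        right = closed_form_androgen(CA0, DELTA_A, 0.0)
        assert left == pytest.approx(right, rel=1e-7)

    def test_monotone_on_each_branch(self):
        t_on = np.linspace(-100.0, -1e-6, 500)
        t_off = np.linspace(0.0, 200.0, 500)
        assert np.all(np.diff(closed_form_androgen(CA0, DELTA_A, t_on)) < 0)
        assert np.all(np.diff(closed_form_androgen(CA0, DELTA_A, t_off)) > 0)

    def test_derivative_never_null_on_either_branch(self):
        grid = np.concatenate((np.linspace(-50, -1e-6, 400),
                               np.linspace(1e-6, 200, 400)))
        dv = closed_form_androgen_derivative(CA0, DELTA_A, grid)
        assert np.all(np.abs(dv) > 0.0)
        assert np.all(dv[grid < 0] < 0) and np.all(dv[grid > 0] > 0)

    def test_solves_the_relaxation_ode(self):
        """The closed form is the exact solution of the androgen channel
        under a single on→off step, verified by direct integration."""
        t0 = -30.0
        sol = solve_ivp(
            lambda t, y: DELTA_A * (CA0 - y) - DELTA_A * CA0 * (t < 0),
            (t0, 170.0), [closed_form_androgen(CA0, DELTA_A, t0)],
            t_eval=np.linspace(t0, 170.0, 200), rtol=1e-12, atol=1e-14,
            max_step=1.0,
        )
        ref = closed_form_androgen(CA0, DELTA_A, sol.t)
        assert np.max(np.abs(sol.y[0] - ref)) < 1e-8

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            closed_form_androgen(-1.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            closed_form_androgen(1.0, 0.0, 0.0)


class TestSimulate:
    def test_i08a_androgen_fixed_point_off_treatment(self):
        sched = TreatmentSchedule((), t_min=0.0, t_max=300.0)
        p = i08a_params()
        traj = simulate("I08A", p, [1.0, 1.0, CA0], sched,
                        np.linspace(0, 300, 50))
        assert np.allclose(traj.states[2], CA0, rtol=1e-9)

    def test_b20_reduces_to_exponential_decay(self):
        md = get_model("B20")
        delta_D = 0.06
        p = md.pvector(dict(p_S=0.3, delta_D=delta_D, gamma_PSA=0.0,
                            delta_PSA=0.1))
        t_half = 1.0 / delta_D
        sched = TreatmentSchedule(((0.0, 2 * t_half),), 0.0, 2 * t_half)
        traj = simulate("B20", p, [0.0, 1.0, 0.0], sched,
                        np.array([0.0, t_half]))
        assert traj.states[1, -1] == pytest.approx(np.exp(-1.0), rel=1e-8)

    def test_matches_closed_form_androgen_across_a_step(self, step_schedule):
        """Piecewise integration reproduces the exact androgen solution to
        better than 1e-6 µg/L over a 200-point grid spanning the switch."""
        p = i08a_params()
        grid = np.linspace(170.0, 370.0, 200)  # switch at t=200
        x0 = np.array([0.0, 0.0, closed_form_androgen(CA0, DELTA_A, -30.0)])
        traj = simulate("I08A", p, x0, step_schedule, grid,
                        solver_opts={"rtol": 1e-10, "atol": 1e-12})
        ref = closed_form_androgen(CA0, DELTA_A, grid - 200.0)
        assert np.max(np.abs(traj.states[2] - ref)) < 1e-6

    def test_state_continuity_at_switches(self, three_cycle_schedule):
        p = default_params("H10")
        x0 = np.array([10.0, 0.5, 0.05])
        for sw in three_cycle_schedule.switch_times():
            eps = 1e-7
            traj = simulate("H10", p, x0, three_cycle_schedule,
                            np.array([0.0, sw - eps, sw + eps]),
                            solver_opts={"method": "RK45"})
            jump = np.abs(traj.states[:, 2] - traj.states[:, 1])
            scale = np.abs(traj.states[:, 1]) + 1.0
            assert np.all(jump / scale < 1e-6)

    def test_tolerance_convergence(self, three_cycle_schedule):
        p = default_params("B20")
        x0 = np.array([0.1, 10.0, 8.0])
        grid = np.linspace(0, three_cycle_schedule.t_max, 60)
        loose = simulate("B20", p, x0, three_cycle_schedule, grid,
                         solver_opts={"rtol": 1e-8, "atol": 1e-10})
        tight = simulate("B20", p, x0, three_cycle_schedule, grid,
                         solver_opts={"rtol": 5e-9, "atol": 5e-11})
        rel = np.max(np.abs(loose.psa - tight.psa) / np.abs(tight.psa))
        assert rel < 1e-6

    def test_h10_nonnegative_trajectories(self, three_cycle_schedule, rng):
        md = get_model("H10")
        for _ in range(5):
            d = md.pdict(default_params("H10"))
            for k in d:
                if k.startswith("mu_"):
                    d[k] = rng.uniform(0, 0.01)
                elif k.startswith("gamma_"):
                    d[k] = rng.uniform(-0.05, 0.03)
            traj = simulate("H10", md.pvector(d), rng.uniform(0.1, 10.0, 3),
                            three_cycle_schedule,
                            np.linspace(0, three_cycle_schedule.t_max, 80))
            assert traj.states.min() >= -1e-8

    def test_linear_fast_path_matches_generic_solver(self,
                                                     three_cycle_schedule):
        p = default_params("H10")
        x0 = np.array([10.0, 0.5, 0.05])
        grid = np.linspace(0, three_cycle_schedule.t_max, 101)
        exact = simulate("H10", p, x0, three_cycle_schedule, grid)
        rk = simulate("H10", p, x0, three_cycle_schedule, grid,
                      solver_opts={"method": "RK45", "rtol": 1e-11,
                                   "atol": 1e-13})
        assert np.allclose(exact.psa, rk.psa, rtol=1e-8)

    def test_invalid_inputs_raise(self, three_cycle_schedule):
        p = default_params("H10")
        with pytest.raises(ValueError):
            simulate("H10", p, [-1.0, 0.0, 0.0], three_cycle_schedule,
                     [0.0, 1.0])
        with pytest.raises(ValueError):
            simulate("H10", p, [1.0, 0.0, 0.0], three_cycle_schedule,
                     [5.0, 1.0])

    def test_blow_up_is_diagnosed(self):
        md = get_model("Z17")
        d = md.pdict(default_params("Z17"))
        sched = TreatmentSchedule(((0.0, 50.0),), 0.0, 100.0)
        # carrying capacity denominator n_P (β − u + 1) → 0 when n_P → 0
        with pytest.raises((SimulationError, ValueError)):
            simulate("Z17", md.pvector(d), [1.0, 0.0, 1.0, 1.0], sched,
                     np.linspace(0, 100, 20))

    def test_trajectory_export_schema(self, three_cycle_schedule, tmp_path):
        p = default_params("B20")
        traj = simulate("B20", p, [0.1, 10.0, 8.0], three_cycle_schedule,
                        np.linspace(0, 500, 20))
        df = traj.to_frame()
        assert set(df.columns) == {"time_days", "state_name", "value"}
        assert set(df.state_name) == {"n_S", "n_D", "c_PSA", "c_PSA_obs"}
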