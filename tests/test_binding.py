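"""Binding-model forward responses and equilibrium constants."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from flimbind.binding import (
    InjectionSchedule,
    Phase,
    SingleStateParams,
    TwoStateParams,
    bli_schedule,
    kd_single,
    kd_two_state,
    single_cycle_schedule,
    single_state_response,
    two_state_response,
)

MINUS_ERK = SingleStateParams(kon=1.2e5, koff=1.1e-4, rmax=1.0)
PLUS_ERK = SingleStateParams(kon=1.2e5, koff=3.3e-4, rmax=1.0)
SEQ_MINUS = TwoStateParams(kon1=6.4e4, koff1=2.0e-3, kon2=8.4e-3, koff2=1.9e-4, rmax=30.0)
SEQ_PLUS = TwoStateParams(kon1=1.1e5, koff1=2.5e-3, kon2=3.7e-3, koff2=1.1e-4, rmax=30.0)

BLI_CONCS = (0.0, 10.9e-9, 31.9e-9, 43.7e-9, 87.5e-9)
SPR_CONCS = (6.2e-9, 18.5e-9, 55.6e-9, 167e-9, 500e-9)


def ode_single_state(params, schedule, t_grid, r0=0.0):
    """Independent oracle: integrate dR/dt numerically phase by phase."""
    bounds = schedule.boundaries_s
    out = np.empty(len(t_grid))
    r = r0
    for i, phase in enumerate(schedule.phases):
        sel = (t_grid >= bounds[i]) & (t_grid <= bounds[i + 1])
        # associate boundary points with the earlier phase like the model does
        sel &= (t_grid < bounds[i + 1]) | (i == len(schedule.phases) - 1)
        def rhs(t, y, c=phase.conc_M):
            return [params.kon * c * (params.rmax - y[0]) - params.koff * y[0]]

        t_eval = np.sort(np.unique(np.concatenate([[bounds[i]], t_grid[sel], [bounds[i + 1]]])))
        sol = solve_ivp(
            rhs,
            (bounds[i], bounds[i + 1]),
            [r],
            t_eval=t_eval,
            rtol=1e-11,
            atol=1e-13,
            method="LSODA",
        )
        lookup = dict(zip(sol.t, sol.y[0]))
        out[sel] = [lookup[t] for t in t_grid[sel]]
        r = sol.y[0][-1]
    return out


class TestSingleStateResponse:
    def test_half_saturation_plateau_at_kd(self):
        kd = kd_single(MINUS_ERK)
        schedule = InjectionSchedule((Phase(2.0e5, kd, "assoc"),))
        t = np.array([2.0e5])
        assert single_state_response(MINUS_ERK, schedule, t)[0] == pytest.approx(
            MINUS_ERK.rmax / 2, rel=1e-3
        )

    def test_dissociation_scalar_arithmetic(self):
        # 100 RU decaying for 180 s at koff = 1.1e-4/s
        schedule = InjectionSchedule((Phase(180.0, 0.0, "dissoc"),))
        value = single_state_response(MINUS_ERK, schedule, np.array([180.0]), r0=100.0)[0]
        assert value == pytest.approx(100.0 * math.exp(-1.1e-4 * 180.0), rel=1e-12)
        assert value == pytest.approx(98.04, abs=0.01)

    def test_matches_ode_oracle_on_bli_schedule(self):
        schedule = bli_schedule(87.5e-9)
        t = np.linspace(0, 360, 181)
        closed = single_state_response(MINUS_ERK, schedule, t)
        numeric = ode_single_state(MINUS_ERK, schedule, t)
        assert np.allclose(closed, numeric, atol=1e-6)

    def test_random_parameters_match_ode_oracle(self):
        rng = np.random.default_rng(42)
        schedule = bli_schedule(50e-9)
        t = np.linspace(0, 360, 61)
        for _ in range(50):
            p = SingleStateParams(
                kon=10 ** rng.uniform(3, 7),
                koff=10 ** rng.uniform(-5, -1),
                rmax=10 ** rng.uniform(-0.5, 2),
            )
            closed = single_state_response(p, schedule, t)
            numeric = ode_single_state(p, schedule, t)
            assert np.allclose(closed, numeric, atol=1e-6)

    def test_time_outside_schedule_rejected(self):
        schedule = bli_schedule(1e-8)
        with pytest.raises(ValueError, match="schedule"):
            single_state_response(MINUS_ERK, schedule, np.array([400.0]))

    def test_response_continuous_across_phases(self):
        schedule = bli_schedule(87.5e-9)
        eps = 1e-9
        before, after = single_state_response(
            MINUS_ERK, schedule, np.array([180.0 - eps, 180.0 + eps])
        )
        assert before == pytest.approx(after, abs=1e-6)


class TestTwoStateResponse:
    def test_decoupling_limit_equals_single_state(self):
        weak = TwoStateParams(
            kon1=1.2e5, koff1=1.1e-4, kon2=1e-12, koff2=1.0, rmax=1.0
        )
        single = SingleStateParams(kon=1.2e5, koff=1.1e-4, rmax=1.0)
        schedule = bli_schedule(87.5e-9)
        t = np.linspace(0, 360, 181)
        assert np.allclose(
            two_state_response(weak, schedule, t),
            single_state_response(single, schedule, t),
            atol=1e-5,
        )

    def test_saturating_association_reaches_rmax(self):
        schedule = InjectionSchedule((Phase(1.0e7, 1e-5, "assoc"),))
        t = np.array([1.0e7])
        assert two_state_response(SEQ_MINUS, schedule, t)[0] == pytest.approx(
            SEQ_MINUS.rmax, rel=1e-4
        )

    def test_equilibrium_matches_linear_algebra_oracle(self):
        # steady state of the 2x2 affine system at C = 500 nM
        c = 500e-9
        p = SEQ_MINUS
        A = np.array(
            [
                [-(p.kon1 * c + p.koff1 + p.kon2), -p.kon1 * c + p.koff2],
                [p.kon2, -p.koff2],
            ]
        )
        b = np.array([p.kon1 * c * p.rmax, 0.0])
        r_eq = np.linalg.solve(A, -b).sum()
        schedule = InjectionSchedule((Phase(5.0e6, c, "assoc"),))
        value = two_state_response(p, schedule, np.array([5.0e6]))[0]
        assert value == pytest.approx(r_eq, abs=1e-6)

    def test_detailed_balance_occupancy(self):
        # equilibrium occupancy equals rmax * C / (C + K_D) with the
        # coupled-equilibrium K_D
        c = 5e-9
        kd = kd_two_state(SEQ_MINUS)
        schedule = InjectionSchedule((Phase(1.0e7, c, "assoc"),))
        value = two_state_response(SEQ_MINUS, schedule, np.array([1.0e7]))[0]
        assert value == pytest.approx(
            SEQ_MINUS.rmax * c / (c + kd), rel=1e-6
        )

    def test_matches_ode_oracle_single_cycle(self):
        schedule = single_cycle_schedule(SPR_CONCS)
        t = np.linspace(0, schedule.total_duration_s, 241)
        exact = two_state_response(SEQ_MINUS, schedule, t)

        bounds = schedule.boundaries_s
        out = np.empty(len(t))
        x = [0.0, 0.0]
        for i, phase in enumerate(schedule.phases):
            def rhs(_, y, c=phase.conc_M, p=SEQ_MINUS):
                r1, r2 = y
                free = p.rmax - r1 - r2
                return [
                    p.kon1 * c * free - p.koff1 * r1 - p.kon2 * r1 + p.koff2 * r2,
                    p.kon2 * r1 - p.koff2 * r2,
                ]

            sel = (t >= bounds[i]) & (t < bounds[i + 1])
            if i == len(schedule.phases) - 1:
                sel = (t >= bounds[i]) & (t <= bounds[i + 1])
            t_eval = np.sort(np.unique(np.concatenate([t[sel], [bounds[i + 1]]])))
            sol = solve_ivp(
                rhs, (bounds[i], bounds[i + 1]), x, t_eval=t_eval,
                rtol=1e-11, atol=1e-14, method="LSODA",
            )
            lookup = dict(zip(sol.t, sol.y.sum(axis=0)))
            out[sel] = [lookup[tt] for tt in t[sel]]
            x = sol.y[:, -1]
        assert np.allclose(exact, out, atol=1e-6)

    def test_bounded_in_zero_rmax(self):
        rng = np.random.default_rng(3)
        schedule = single_cycle_schedule(SPR_CONCS)
        t = np.linspace(0, schedule.total_duration_s, 200)
        for _ in range(20):
            p = TwoStateParams(
                kon1=10 ** rng.uniform(3, 7),
                koff1=10 ** rng.uniform(-5, -1),
                kon2=10 ** rng.uniform(-5, 0),
                koff2=10 ** rng.uniform(-6, -1),
                rmax=30.0,
            )
            r = two_state_response(p, schedule, t)
            assert np.all(r >= -1e-9) and np.all(r <= p.rmax + 1e-9)


class TestEquilibriumConstants:
    def test_kd_single_published_values(self):
        assert kd_single(MINUS_ERK) * 1e12 == pytest.approx(920, rel=0.01)
        assert kd_single(PLUS_ERK) * 1e12 == pytest.approx(2750, rel=0.02)
        assert kd_single(PLUS_ERK) * 1e12 == pytest.approx(2700, rel=0.10)

    def test_kd_single_unity_when_rates_equal(self):
        assert kd_single(SingleStateParams(kon=5.0, koff=5.0, rmax=1.0)) == 1.0

    def test_kd_two_state_published_values(self):
        assert kd_two_state(SEQ_MINUS) * 1e12 == pytest.approx(691, abs=1)
        assert kd_two_state(SEQ_MINUS) * 1e12 == pytest.approx(720, rel=0.10)
        assert kd_two_state(SEQ_PLUS) * 1e12 == pytest.approx(656, abs=1)
        assert kd_two_state(SEQ_PLUS) * 1e12 == pytest.approx(650, rel=0.10)

    def test_kd_two_state_decoupling_limit(self):
        p = TwoStateParams(kon1=1e5, koff1=1e-3, kon2=1e-15, koff2=1e-3, rmax=1.0)
        assert kd_two_state(p) == pytest.approx(1e-8, rel=1e-9)


class TestSchedules:
    def test_json_round_trip(self):
        schedule = single_cycle_schedule(SPR_CONCS)
        again = InjectionSchedule.from_json(schedule.to_json())
        assert again == schedule

    def test_validation(self):
        with pytest.raises(ValueError):
            InjectionSchedule(())
        with pytest.raises(ValueError):
            Phase(-1.0, 1e-9)
        with pytest.raises(ValueError):
            Phase(10.0, -1e-9)
        with pytest.raises(ValueError):
            SingleStateParams(kon=0.0, koff=1e-4, rmax=1.0)
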