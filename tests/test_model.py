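"""Core analytic machinery: rate composition, exact kinetics, crossing solvers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from hybridcycle import (
    UNREACHABLE,
    BooleanRegulators,
    amount_crossing_time,
    concentration_crossing_time,
    cyclin_at,
    default_config,
    effective_rates,
    mass_at,
)
from hybridcycle.model import CyclinRates, CyclinRateParams


CFG = default_config()
STATE_REGS = {s.index: s.regulators for s in CFG.states}


class TestEffectiveRates:
    def test_state1_cyclin_a_effective_constants(self):
        # G1a: TFE=TFB=Cdc20A=0, Cdh1=1 -> ks = k'_sa = 5, kd = k'_da + k'''_da = 1.4
        ks, kd = effective_rates("A", STATE_REGS[1], CFG.rate_params)
        assert ks == pytest.approx(5.0)
        assert kd == pytest.approx(1.4)

    def test_no_active_regulators_gives_basal_rates(self):
        r = CFG.rate_params.a
        ks, kd = effective_rates("A", BooleanRegulators(), CFG.rate_params)
        assert ks == pytest.approx(r.ks_basal)
        assert kd == pytest.approx(r.kd_basal)

    def test_state8_cyclin_b_degradation_sums_cdc20b_increment(self):
        # Anaphase: Cdc20B on, Cdh1 off -> kd = k'_db + k''_db
        r = CFG.rate_params.b
        _, kd = effective_rates("B", STATE_REGS[8], CFG.rate_params)
        assert kd == pytest.approx(r.kd_basal + r.kd_cdc20b)

    def test_zero_effective_kd_is_configuration_error(self):
        params = CyclinRateParams(
            a=CyclinRates(ks_basal=1.0, kd_cdh1=1.0),  # kd only via Cdh1
            b=CyclinRates(ks_basal=1.0, kd_basal=1.0),
            e=CyclinRates(ks_basal=1.0, kd_basal=1.0),
        )
        with pytest.raises(ValueError, match="kd > 0"):
            effective_rates("A", BooleanRegulators(), params)

    @pytest.mark.parametrize("cyclin", ["A", "B", "E"])
    @pytest.mark.parametrize("flag", ["tfe", "tfb", "scf", "cdc20a", "cdc20b", "cdh1"])
    def test_turning_on_any_regulator_never_decreases_rates(self, cyclin, flag):
        # keep some degradation route on so both calls are well-defined
        base = BooleanRegulators(scf=1, cdh1=1)
        on = BooleanRegulators(**{**base.__dict__, flag: 1})
        base_off = BooleanRegulators(**{**base.__dict__, flag: 0})
        ks0, kd0 = effective_rates(cyclin, base_off, CFG.rate_params)
        ks1, kd1 = effective_rates(cyclin, on, CFG.rate_params)
        assert ks1 >= ks0
        assert kd1 >= kd0


class TestCyclinAt:
    def test_fixed_point_at_steady_state(self):
        assert cyclin_at(2.5, 5.0, 2.0, 13.7) == pytest.approx(2.5)

    def test_long_time_asymptote_state1_constants(self):
        assert cyclin_at(1.0, 5.0, 1.4, 1e4) == pytest.approx(25 / 7, rel=1e-12)

    def test_one_hour_value_matches_numerical_integration(self):
        sol = solve_ivp(lambda t, y: 5.0 - 1.4 * y, (0, 1), [1.0],
                        rtol=1e-12, atol=1e-14, dense_output=True)
        assert cyclin_at(1.0, 5.0, 1.4, 1.0) == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert cyclin_at(1.0, 5.0, 1.4, 1.0) == pytest.approx(2.9373, abs=1e-4)

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            cyclin_at(1.0, 1.0, 1.0, -0.1)

    @given(c0=st.floats(0.01, 100), ks=st.floats(0, 50), kd=st.floats(0.01, 5),
           dt=st.floats(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_trajectory_stays_between_start_and_asymptote(self, c0, ks, kd, dt):
        c = cyclin_at(c0, ks, kd, dt)
        lo, hi = sorted((c0, ks / kd))
        assert lo - 1e-9 <= c <= hi + 1e-9


class TestMassAt:
    def test_zero_interval_returns_birth_mass(self):
        assert mass_at(3.0, 0.05, 0.0) == 3.0

    def test_doubling_time(self):
        g = 0.0315
        assert mass_at(7.7, g, math.log(2) / g) == pytest.approx(15.4)

    def test_direct_evaluation(self):
        assert mass_at(3.0, 0.0315, 10.0) == pytest.approx(3.0 * math.exp(0.315))
        assert mass_at(3.0, 0.0315, 10.0) == pytest.approx(4.11, abs=0.005)


class TestConcentrationCrossing:
    def test_already_at_threshold_returns_zero(self):
        assert concentration_crossing_time(5.0, 1.0, 1.0, 5.0, "down") == 0.0
        assert concentration_crossing_time(5.0, 10.0, 1.0, 5.0, "up") == 0.0

    def test_downward_crossing_closed_form(self):
        t = concentration_crossing_time(10.0, 1.0, 1.0, 5.0, "down")
        assert t == pytest.approx(math.log(9 / 4), rel=1e-12)
        # independent check by bisection on the trajectory
        t_bis = bisect(lambda u: cyclin_at(10, 1, 1, u) - 5.0, 0.0, 10.0, xtol=1e-12)
        assert t == pytest.approx(t_bis, abs=1e-9)

    def test_threshold_beyond_asymptote_unreachable(self):
        assert concentration_crossing_time(10.0, 1.0, 1.0, 0.5, "down") == UNREACHABLE
        assert concentration_crossing_time(1.0, 1.0, 1.0, 5.0, "up") == UNREACHABLE

    @given(c0=st.floats(0.1, 50), ks=st.floats(0, 50), kd=st.floats(0.05, 5),
           frac=st.floats(0.05, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_finite_crossing_satisfies_trajectory_equation(self, c0, ks, kd, frac):
        css = ks / kd
        theta = c0 + frac * (css - c0)  # strictly between start and asymptote
        if abs(theta - c0) < 1e-9 or abs(theta - css) < 1e-12:
            return
        direction = "up" if css > c0 else "down"
        t = concentration_crossing_time(c0, ks, kd, theta, direction)
        assert math.isfinite(t)
        assert cyclin_at(c0, ks, kd, t) == pytest.approx(theta, abs=1e-9)


class TestAmountCrossing:
    def test_zero_growth_reduces_to_concentration_solver(self):
        t_amount = amount_crossing_time(1.0, 5.0, 1.4, 2.0, 0.0, 5.0, "up")
        t_conc = concentration_crossing_time(1.0, 5.0, 1.4, 5.0 / 2.0, "up")
        assert t_amount == pytest.approx(t_conc, abs=1e-12)

    def test_already_met_amount_returns_zero(self):
        assert amount_crossing_time(5.0, 1.0, 1.0, 10.0, 0.03, 20.0, "up") == 0.0

    def test_rising_cyclin_e_amount_matches_grid_scan_oracle(self, cfg):
        # state-2-like setting: TFE-driven cyclin E, growing mass
        kse, kde = 2.1, 0.2
        c0, m0, gamma, theta = 0.25, 3.2, cfg.gamma, 21.25
        t = amount_crossing_time(c0, kse, kde, m0, gamma, theta, "up")
        assert math.isfinite(t)
        grid = np.linspace(0, 2 * t + 1.0, 2_000_001)
        amounts = (kse / kde + (c0 - kse / kde) * np.exp(-kde * grid)) * m0 * np.exp(gamma * grid)
        t_grid = grid[np.argmax(amounts >= theta)]
        assert t == pytest.approx(t_grid, abs=1e-5)

    @given(c0=st.floats(0.1, 10), ks=st.floats(0.5, 30), kd=st.floats(0.05, 3),
           m0=st.floats(0.5, 10), ratio=st.floats(1.1, 30))
    @settings(max_examples=100, deadline=None)
    def test_crossing_satisfies_amount_equation(self, c0, ks, kd, m0, ratio):
        gamma = 0.0347
        theta = c0 * m0 * ratio
        t = amount_crossing_time(c0, ks, kd, m0, gamma, theta, "up")
        assert math.isfinite(t)  # growing mass + positive synthesis: always reachable
        amount = cyclin_at(c0, ks, kd, t) * mass_at(m0, gamma, t)
        assert amount == pytest.approx(theta, abs=1e-8 * theta)


class TestStateTable:
    def test_nine_states_with_correct_exit_conditions(self, cfg):
        assert sorted(s.index for s in cfg.states) == list(range(1, 10))
        kinds = {s.index: s.exit_condition.value for s in cfg.states}
        assert all(kinds[i] == "threshold" for i in (2, 3, 5, 9))
        assert all(kinds[i] == "timer" for i in (1, 4, 6, 7, 8))
        tdet = {s.index: s.t_det for s in cfg.states}
        assert all(tdet[i] == 0.0 for i in (1, 6, 7, 8))
        assert tdet[4] == 7.0

    def test_g1a_waiting_time_mean_is_two_hours(self, cfg):
        lam = {s.index: s.lam for s in cfg.states}
        assert lam[1] == 2.0
        assert lam[2] == 0.0  # no stochastic component out of state 2

    def test_threshold_quartet_values(self, cfg):
        assert cfg.thresholds == {
            "theta_e": 21.25, "theta_a": 12.5, "theta_b_hi": 80.0, "theta_b_lo": 3.0,
        }
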