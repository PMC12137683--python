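"""Thermistor conversion, PID control and the two-node thermal plant."""

import math

import numpy as np
import pytest

import rockerflow as rf
from rockerflow.thermal import (
    PIDGains,
    PIDState,
    ThermalPlant,
    ThermistorModel,
    fit_plant,
    pid_step,
    simulate_step_response,
    simulate_with_duty,
    thermistor_to_temperature,
)


class TestThermistor:
    def test_beta_equation_fixed_point(self):
        m = ThermistorModel()
        counts = m.counts_at(25.0)  # R = R0 at T0 = 298.15 K
        assert thermistor_to_temperature(counts, m) == pytest.approx(25.0, abs=1e-9)

    def test_half_resistance_value(self):
        # R = 5 kOhm with R0 = 10 kOhm, T0 = 298.15 K, B = 3950 K:
        # 1/(1/298.15 + ln(0.5)/3950) = 314.61 K = 41.46 C.
        m = ThermistorModel()
        frac = 5e3 / (5e3 + m.r_divider)
        t = thermistor_to_temperature(frac * m.adc_full_scale, m)
        assert t == pytest.approx(41.46, abs=0.01)

    @pytest.mark.parametrize("counts", [0, 1023, -3, 2000])
    def test_rail_counts_flag_sensor_fault(self, counts):
        with pytest.raises(ValueError, match="sensor fault"):
            thermistor_to_temperature(counts, ThermistorModel())

    def test_ntc_resistance_decreases_with_temperature(self):
        m = ThermistorModel()
        rs = [m.resistance_at(t) for t in (0.0, 25.0, 60.0)]
        assert rs[0] > rs[1] > rs[2]

    def test_roundtrip_through_divider(self):
        m = ThermistorModel()
        for t_true in (4.0, 21.0, 37.0, 80.0):
            assert thermistor_to_temperature(m.counts_at(t_true), m) == pytest.approx(
                t_true, abs=1e-9
            )


class TestPidStep:
    def test_zero_error_zero_history_gives_zero_duty(self):
        duty, _ = pid_step(PIDGains(), 37.0, 37.0, PIDState())
        assert duty == 0.0

    def test_large_error_saturates(self):
        duty, _ = pid_step(PIDGains(kp=1.0), 37.0, 0.0, PIDState())
        assert duty == 1.0
        duty, _ = pid_step(PIDGains(kp=1.0), 4.0, 40.0, PIDState())
        assert duty == -1.0

    def test_integral_accumulates_closed_form(self):
        gains = PIDGains(kp=0.0, ki=0.01, kd=0.0, sample_interval=2.0)
        e, n = 0.5, 7
        state = PIDState()
        for _ in range(n):
            duty, state = pid_step(gains, e, 0.0, state)
        assert state.integral == pytest.approx(gains.ki * e * n * gains.sample_interval)
        assert duty == pytest.approx(gains.ki * e * n * gains.sample_interval)

    def test_antiwindup_clamps_integral(self):
        gains = PIDGains(kp=0.0, ki=1.0, integral_limit=0.3)
        state = PIDState()
        for _ in range(100):
            _, state = pid_step(gains, 10.0, 0.0, state)
        assert state.integral == pytest.approx(0.3)


class TestPlant:
    def test_relaxation_to_ambient(self):
        # Actuator off: the hotter envelope decays monotonically and
        # neither node undershoots ambient (maximum principle for the
        # two-node system).
        plant = ThermalPlant()
        times = np.arange(0, 1800.0, 1.0)
        duty = np.zeros_like(times)
        plate, water = simulate_with_duty(plant, times, duty, 50.0, 45.0)
        envelope = np.maximum(plate, water)
        assert np.all(np.diff(envelope) <= 1e-9)
        assert np.all(plate >= plant.ambient_c - 1e-9)
        assert np.all(water >= plant.ambient_c - 1e-9)
        assert water[-1] < plant.ambient_c + 1.0

    def test_flat_traces_at_ambient_setpoint(self):
        plant = ThermalPlant()
        resp = simulate_step_response(plant, PIDGains(), plant.ambient_c, 120.0)
        assert np.abs(resp.water_c - plant.ambient_c).max() < 1e-6

    def test_water_lags_plate_when_heating(self):
        resp = simulate_step_response(ThermalPlant(), PIDGains(), 37.0, 600.0)
        crossing_plate = resp.times[np.argmax(resp.plate_c > 30.0)]
        crossing_water = resp.times[np.argmax(resp.water_c > 30.0)]
        assert crossing_plate < crossing_water

    def test_integral_action_removes_steady_state_error(self):
        resp = simulate_step_response(ThermalPlant(), PIDGains(), 37.0, 3600.0)
        assert abs(resp.water_c[-1] - 37.0) < 0.05

    def test_proportional_only_droop_matches_algebra(self):
        # kd = ki = 0: the closed loop settles at the solution of
        # kp*(S - Tw)*P_heat = heat needed to hold Tw, solved from the
        # two-node steady state (independent algebraic oracle).
        plant = ThermalPlant()
        gains = PIDGains(kp=0.05, ki=0.0, kd=0.0)
        S = 37.0
        # Steady state: Tp = Tw + (k_wa/k_pw)(Tw - Ta);
        # P = k_pa (Tp - Ta) + k_wa (Tw - Ta) = kp (S - Tw) P_heat.
        kpw, kpa, kwa = plant.k_plate_water, plant.k_plate_ambient, plant.k_water_ambient
        Ta, Ph = plant.ambient_c, plant.heat_power_w
        # (Tw - Ta) * [kpa*(1 + kwa/kpw) + kwa] = kp*Ph*(S - Tw)
        a = kpa * (1 + kwa / kpw) + kwa
        tw_expected = (gains.kp * Ph * S + a * Ta) / (a + gains.kp * Ph)
        resp = simulate_step_response(plant, gains, S, 7200.0)
        assert resp.water_c[-1] == pytest.approx(tw_expected, abs=0.05)
        assert abs(tw_expected - S) > 0.5  # a genuine droop, not a degenerate check

    def test_cooling_setpoint_below_device_floor_rejected(self):
        with pytest.raises(ValueError):
            simulate_step_response(ThermalPlant(), PIDGains(), -20.0, 60.0)

    def test_divergence_guard_aborts_with_diagnostic(self):
        # A power-limited Peltier cannot diverge, so trip the guard with
        # an absurdly overpowered actuator and destabilising gains.
        plant = ThermalPlant(heat_power_w=1e6, cool_power_w=1e6)
        gains = PIDGains(kp=50.0, ki=0.0, sample_interval=30.0)
        with pytest.raises(RuntimeError, match="diverged"):
            simulate_step_response(plant, gains, 37.0, 7200.0)

    def test_settling_time_same_order_as_bench(self):
        # Heating to 37 C settles in minutes (order of the reported
        # ~8 min), not seconds or hours.
        resp = simulate_step_response(ThermalPlant(), PIDGains(), 37.0, 3600.0)
        inside = np.abs(resp.water_c - 37.0) < 0.5
        # last time the trace was outside the band
        settle = resp.times[np.where(~inside)[0][-1]] + 1.0 if not inside.all() else 0.0
        assert 60.0 < settle < 2400.0


class TestParameterRecovery:
    def test_two_node_fit_recovers_truth_within_ten_percent(self):
        from rockerflow.fixtures import FixtureSpec, gen_temperature_trace

        truth = ThermalPlant()
        spec = FixtureSpec(
            kind="temperature_trace",
            params={"plant": truth, "setpoint_c": 37.0, "duration_s": 900.0},
            noise_sigma=0.05,
            sample_rate_hz=1.0,
            seed=42,
        )
        trace = gen_temperature_trace(spec)
        start = ThermalPlant(c_water=truth.c_water * 1.5, k_plate_water=truth.k_plate_water * 0.6)
        fitted = fit_plant(
            trace.times, trace.plate_c, trace.water_c, trace.duty, start
        )
        assert fitted.c_water == pytest.approx(truth.c_water, rel=0.10)
        assert fitted.k_plate_water == pytest.approx(truth.k_plate_water, rel=0.10)
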