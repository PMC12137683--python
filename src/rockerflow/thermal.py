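"""Lumped-parameter Peltier/PID thermal simulation.

The sample holder is reduced to two thermal nodes: the aluminium
platform ("plate"), driven directly by the Peltier module, and the
water in the wells, coupled to the plate through a conductance.  Both
nodes leak to ambient.  A discrete PID controller modulates the Peltier
duty cycle; the 490 Hz PWM drive is far faster than any thermal time
constant, so only its duty-cycle mean enters the plant.  Asymmetric
heating/cooling power limits stand in for Peltier device physics.

    C_p dT_p/dt = P(duty) - k_pw (T_p - T_w) - k_pa (T_p - T_amb)
    C_w dT_w/dt =          k_pw (T_p - T_w) - k_wa (T_w - T_amb)

The thermistor model converts ADC counts from a resistive divider to
temperature through the NTC beta equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ThermalPlant",
    "PIDGains",
    "PIDState",
    "ThermistorModel",
    "StepResponse",
    "thermistor_to_temperature",
    "pid_step",
    "simulate_step_response",
    "simulate_with_duty",
    "fit_plant",
]

#: Device cooling floor: -9 C absolute, or 35 C below ambient.
MIN_TEMPERATURE_C = -9.0
MAX_BELOW_AMBIENT_C = 35.0


@dataclass(frozen=True)
class ThermalPlant:
    """Two-node plant: plate (Peltier side) and water (sample side)."""

    c_plate: float = 180.0  # J/K, ~0.2 kg aluminium holder
    c_water: float = 120.0  # J/K, ~28 mL across four wells
    k_plate_water: float = 1.5  # W/K
    k_plate_ambient: float = 0.8  # W/K
    k_water_ambient: float = 0.2  # W/K
    ambient_c: float = 21.0
    heat_power_w: float = 40.0  # Peltier limit, heating direction
    cool_power_w: float = 25.0  # Peltier limit, cooling direction

    def __post_init__(self) -> None:
        if self.c_plate <= 0 or self.c_water <= 0:
            raise ValueError("heat capacities must be positive")
        for k in (self.k_plate_water, self.k_plate_ambient, self.k_water_ambient):
            if k < 0:
                raise ValueError("conductances must be non-negative")
        if self.heat_power_w <= 0 or self.cool_power_w <= 0:
            raise ValueError("actuator power limits must be positive")

    def power(self, duty: float) -> float:
        """Mean Peltier power (W) for a signed duty cycle in [-1, 1]."""
        return duty * (self.heat_power_w if duty >= 0 else self.cool_power_w)

    def min_setpoint_c(self) -> float:
        """Coolest reachable setpoint given the device floor."""
        return max(MIN_TEMPERATURE_C, self.ambient_c - MAX_BELOW_AMBIENT_C)


@dataclass(frozen=True)
class PIDGains:
    """Discrete PID gains; output is a duty cycle clamped to [-1, 1]."""

    kp: float = 0.25  # duty per C
    ki: float = 0.004  # duty per (C s)
    kd: float = 0.0  # duty s per C
    output_limit: float = 1.0
    sample_interval: float = 1.0  # s
    integral_limit: float = 1.0  # anti-windup clamp on the integral term

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample interval must be positive")
        if self.output_limit <= 0 or self.integral_limit < 0:
            raise ValueError("limits must be positive")


@dataclass
class PIDState:
    integral: float = 0.0  # integral *term* (ki already applied)
    prev_error: float | None = None


@dataclass(frozen=True)
class ThermistorModel:
    """NTC thermistor in a resistive divider read by an ADC.

    counts/full_scale = R_th / (R_th + R_divider); the beta equation
    R(T) = R0 exp(B (1/T - 1/T0)) is inverted for T.
    """

    r0: float = 10e3  # ohm at t0
    t0_k: float = 298.15
    beta: float = 3950.0  # K
    r_divider: float = 10e3
    adc_full_scale: int = 1023

    def __post_init__(self) -> None:
        for v in (self.r0, self.t0_k, self.beta, self.r_divider, self.adc_full_scale):
            if v <= 0:
                raise ValueError("thermistor model parameters must be positive")

    def resistance_at(self, temperature_c: float) -> float:
        t_k = temperature_c + 273.15
        return self.r0 * math.exp(self.beta * (1.0 / t_k - 1.0 / self.t0_k))

    def counts_at(self, temperature_c: float) -> float:
        r = self.resistance_at(temperature_c)
        return self.adc_full_scale * r / (r + self.r_divider)


def thermistor_to_temperature(adc_counts: float, model: ThermistorModel) -> float:
    """Temperature (C) from raw ADC counts.

    Raises
    ------
    ValueError
        Counts at either rail (0 or full scale) indicate a shorted or
        disconnected sensor and are rejected as a sensor fault.
    """
    if adc_counts <= 0 or adc_counts >= model.adc_full_scale:
        raise ValueError(
            f"sensor fault: ADC counts {adc_counts!r} at the rail "
            f"(valid range is (0, {model.adc_full_scale}))"
        )
    frac = adc_counts / model.adc_full_scale
    r = model.r_divider * frac / (1.0 - frac)
    t_k = 1.0 / (1.0 / model.t0_k + math.log(r / model.r0) / model.beta)
    return t_k - 273.15


def pid_step(
    gains: PIDGains, setpoint: float, measured: float, state: PIDState
) -> tuple[float, PIDState]:
    """One discrete PID update; returns (duty in [-limit, limit], new state).

    The integral term is clamped (anti-windup) and the derivative acts
    on the error difference over one sample interval.
    """
    dt = gains.sample_interval
    error = setpoint - measured
    integral = state.integral + gains.ki * error * dt
    integral = max(-gains.integral_limit, min(gains.integral_limit, integral))
    derivative = 0.0
    if gains.kd != 0.0 and state.prev_error is not None:
        derivative = gains.kd * (error - state.prev_error) / dt
    out = gains.kp * error + integral + derivative
    out = max(-gains.output_limit, min(gains.output_limit, out))
    return out, PIDState(integral=integral, prev_error=error)


@dataclass
class StepResponse:
    """Simulated temperature traces under PID control."""

    times: np.ndarray  # s
    plate_c: np.ndarray
    water_c: np.ndarray
    duty: np.ndarray
    setpoint_c: float
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.times,
                "T_plate_C": self.plate_c,
                "T_water_C": self.water_c,
                "duty": self.duty,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _plant_rhs(plant: ThermalPlant, t_p: float, t_w: float, power: float):
    dp = (
        power
        - plant.k_plate_water * (t_p - t_w)
        - plant.k_plate_ambient * (t_p - plant.ambient_c)
    ) / plant.c_plate
    dw = (
        plant.k_plate_water * (t_p - t_w)
        - plant.k_water_ambient * (t_w - plant.ambient_c)
    ) / plant.c_water
    return dp, dw


def _integrate_interval(plant, t_p, t_w, power, duration, dt_max=0.25):
    """Heun (RK2) sub-steps across one controller interval."""
    remaining = duration
    while remaining > 1e-12:
        dt = min(dt_max, remaining)
        dp1, dw1 = _plant_rhs(plant, t_p, t_w, power)
        dp2, dw2 = _plant_rhs(plant, t_p + dt * dp1, t_w + dt * dw1, power)
        t_p += 0.5 * dt * (dp1 + dp2)
        t_w += 0.5 * dt * (dw1 + dw2)
        remaining -= dt
    return t_p, t_w


def simulate_step_response(
    plant: ThermalPlant,
    gains: PIDGains,
    setpoint_c: float,
    duration_s: float,
    initial_c: float | None = None,
    sensor: str = "water",
) -> StepResponse:
    """Closed-loop step response of the two-node plant under PID control.

    The controller samples the chosen sensor ("water" by default, the
    in-well probe; "plate" for the platform thermistor) every
    ``gains.sample_interval`` seconds and holds the duty across the
    interval (zero-order hold, the PWM duty-cycle mean).

    Raises
    ------
    RuntimeError
        If the loop diverges (temperatures leave a wide sanity band).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if setpoint_c < plant.min_setpoint_c():
        raise ValueError(
            f"setpoint {setpoint_c} C below the device floor "
            f"{plant.min_setpoint_c()} C"
        )
    t_p = t_w = plant.ambient_c if initial_c is None else initial_c
    state = PIDState()
    dt = gains.sample_interval
    n = int(math.ceil(duration_s / dt)) + 1
    times = np.arange(n) * dt
    plate = np.empty(n)
    water = np.empty(n)
    duty = np.empty(n)
    for k in range(n):
        plate[k] = t_p
        water[k] = t_w
        measured = t_w if sensor == "water" else t_p
        d, state = pid_step(gains, setpoint_c, measured, state)
        duty[k] = d
        if k + 1 < n:
            t_p, t_w = _integrate_interval(plant, t_p, t_w, plant.power(d), dt)
            if not (-100.0 < t_p < 250.0 and -100.0 < t_w < 250.0):
                raise RuntimeError(
                    f"thermal loop diverged at t={times[k]:.1f} s "
                    f"(plate={t_p:.1f} C, water={t_w:.1f} C); check the PID gains"
                )
    return StepResponse(
        times=times,
        plate_c=plate,
        water_c=water,
        duty=duty,
        setpoint_c=setpoint_c,
        meta={"sensor": sensor, "ambient_c": plant.ambient_c},
    )


def simulate_with_duty(
    plant: ThermalPlant,
    times: np.ndarray,
    duty: np.ndarray,
    initial_plate_c: float,
    initial_water_c: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Open-loop plant response to a recorded duty sequence (zero-order hold)."""
    t_p = float(initial_plate_c)
    t_w = float(initial_water_c)
    plate = np.empty(len(times))
    water = np.empty(len(times))
    for k in range(len(times)):
        plate[k] = t_p
        water[k] = t_w
        if k + 1 < len(times):
            t_p, t_w = _integrate_interval(
                plant, t_p, t_w, plant.power(float(duty[k])), float(times[k + 1] - times[k])
            )
    return plate, water


def fit_plant(
    times: np.ndarray,
    plate_obs: np.ndarray,
    water_obs: np.ndarray,
    duty: np.ndarray,
    template: ThermalPlant,
    fit_params: Sequence[str] = ("c_water", "k_plate_water"),
) -> ThermalPlant:
    """Recover plant parameters from a recorded (noisy) step response.

    Re-simulates the two-node plant open loop with the recorded duty
    sequence and least-squares-fits the named parameters so the
    simulated plate and water traces match the observations.  Remaining
    parameters are taken from ``template``.
    """
    x0 = np.array([getattr(template, p) for p in fit_params], dtype=float)

    def residuals(x):
        plant = replace(template, **{p: float(v) for p, v in zip(fit_params, x)})
        plate, water = simulate_with_duty(
            plant, times, duty, plate_obs[0], water_obs[0]
        )
        return np.concatenate((plate - plate_obs, water - water_obs))

    res = least_squares(residuals, x0, bounds=(1e-6, np.inf), xtol=1e-12, ftol=1e-12)
    return replace(template, **{p: float(v) for p, v in zip(fit_params, res.x)})
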