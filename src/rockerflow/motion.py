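"""Seesaw motion profiles, RPM conversion and resonance prediction.

The rocker tilts the plate periodically between +alpha and -alpha at a
(maximum) angular speed omega.  With unlimited stepper acceleration the
tilt angle is an exact triangle wave of period ``T = 4*alpha/omega``;
with a finite acceleration limit ``a`` the angular velocity becomes a
trapezoid and the period stretches to ``T = 4*alpha/omega + 2*omega/a``
(each of the two reversals takes ``2*omega/a`` but also shortens the
cruise by ``omega/a``).  If ``a < omega**2/(2*alpha)`` the cruise speed
is never reached and the motion degenerates to bang-bang acceleration
with period ``4*sqrt(2*alpha/a)``.

Angles are stored in radians internally; the user-facing settings are in
degrees, matching the device front panel.  Phase convention:
``theta(0) = +alpha`` (full clockwise tilt, right end down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "MotionSettings",
    "MotionProfile",
    "make_motion_profile",
    "rocking_speed_to_rpm",
    "resonance_velocity",
    "predicted_resonant_speed",
]

#: Device limits: tilt amplitude 1..19 deg, speed 1..99 deg/s.
ANGLE_LIMITS_DEG = (1.0, 19.0)
SPEED_LIMITS_DEG_S = (1.0, 99.0)


@dataclass(frozen=True)
class MotionSettings:
    """Front-panel motion settings (degrees / degrees-per-second).

    ``enforce_limits=False`` lifts the hardware range checks for
    simulation-only studies (e.g. sweeping slightly beyond the 99 deg/s
    panel limit); amplitude and speed must still be positive.
    """

    max_angle_deg: float
    max_speed_deg_s: float
    max_accel_deg_s2: float | None = None  # None = unlimited (instant reversal)
    enforce_limits: bool = True

    def __post_init__(self) -> None:
        if self.max_angle_deg <= 0 or self.max_speed_deg_s <= 0:
            raise ValueError("rocking angle and speed must be positive")
        if self.enforce_limits:
            lo, hi = ANGLE_LIMITS_DEG
            if not (lo <= self.max_angle_deg <= hi):
                raise ValueError(
                    f"max rocking angle {self.max_angle_deg!r} deg outside the "
                    f"device range [{lo}, {hi}] deg"
                )
            lo, hi = SPEED_LIMITS_DEG_S
            if not (lo <= self.max_speed_deg_s <= hi):
                raise ValueError(
                    f"max rocking speed {self.max_speed_deg_s!r} deg/s outside "
                    f"the device range [{lo}, {hi}] deg/s"
                )
        if self.max_accel_deg_s2 is not None and self.max_accel_deg_s2 <= 0:
            raise ValueError("max acceleration must be positive (or None)")


@dataclass(frozen=True)
class MotionProfile:
    """Periodic tilt trajectory theta(t), theta_dot(t), theta_ddot(t) in radians."""

    period: float
    theta: Callable[[np.ndarray | float], np.ndarray | float]
    theta_dot: Callable[[np.ndarray | float], np.ndarray | float]
    theta_ddot: Callable[[np.ndarray | float], np.ndarray | float]
    settings: MotionSettings


def _triangle_profile(alpha: float, omega: float) -> tuple[float, Callable, Callable, Callable]:
    # Unlimited acceleration: theta is a triangle wave starting at +alpha.
    period = 4.0 * alpha / omega

    def theta(t):
        s = np.mod(np.asarray(t, dtype=float), period)
        half = period / 2.0
        out = np.where(s < half, alpha - omega * s, -alpha + omega * (s - half))
        return out if out.ndim else float(out)

    def theta_dot(t):
        s = np.mod(np.asarray(t, dtype=float), period)
        out = np.where(s < period / 2.0, -omega, omega)
        return out if out.ndim else float(out)

    def theta_ddot(t):
        s = np.asarray(t, dtype=float)
        out = np.zeros_like(s)
        return out if out.ndim else 0.0

    return period, theta, theta_dot, theta_ddot


def _piecewise_profile(
    alpha: float, omega: float, accel: float
) -> tuple[float, Callable, Callable, Callable]:
    """Trapezoidal-velocity profile starting at theta(0)=+alpha, theta_dot(0)=0."""
    if accel < omega**2 / (2.0 * alpha):
        # Cruise speed unreachable: bang-bang acceleration between the stops.
        omega = math.sqrt(2.0 * alpha * accel)  # actual peak speed
        t_ramp = omega / accel
        t_cruise = 0.0
    else:
        t_ramp = omega / accel
        t_cruise = (2.0 * alpha - omega**2 / accel) / omega
    # Segment boundaries over one period, starting at +alpha with zero speed:
    # [0, t_ramp)               accel -a, from theta_dot=0 to -omega
    # [t1, t1+t_cruise)         cruise -omega
    # [t2, t2+2*t_ramp)         accel +a, -omega -> +omega (bottom reversal)
    # [t3, t3+t_cruise)         cruise +omega
    # [t4, t4+t_ramp)           accel -a, +omega -> 0, ends at +alpha
    t1 = t_ramp
    t2 = t1 + t_cruise
    t3 = t2 + 2.0 * t_ramp
    t4 = t3 + t_cruise
    period = t4 + t_ramp

    # Angles at the segment boundaries.
    th1 = alpha - 0.5 * accel * t_ramp**2
    th2 = th1 - omega * t_cruise
    th3 = th2  # symmetric reversal returns to the same angle with +omega
    th4 = th3 + omega * t_cruise

    def _eval(t, order):
        s = np.mod(np.asarray(t, dtype=float), period)
        th = np.empty_like(s)
        dth = np.empty_like(s)
        ddth = np.empty_like(s)

        m = s < t1
        u = s[m]
        th[m] = alpha - 0.5 * accel * u**2
        dth[m] = -accel * u
        ddth[m] = -accel

        m = (s >= t1) & (s < t2)
        u = s[m] - t1
        th[m] = th1 - omega * u
        dth[m] = -omega
        ddth[m] = 0.0

        m = (s >= t2) & (s < t3)
        u = s[m] - t2
        th[m] = th2 - omega * u + 0.5 * accel * u**2
        dth[m] = -omega + accel * u
        ddth[m] = accel

        m = (s >= t3) & (s < t4)
        u = s[m] - t3
        th[m] = th3 + omega * u
        dth[m] = omega
        ddth[m] = 0.0

        m = s >= t4
        u = s[m] - t4
        th[m] = th4 + omega * u - 0.5 * accel * u**2
        dth[m] = omega - accel * u
        ddth[m] = -accel

        out = (th, dth, ddth)[order]
        return out if out.ndim else float(out)

    return (
        period,
        lambda t: _eval(t, 0),
        lambda t: _eval(t, 1),
        lambda t: _eval(t, 2),
    )


def make_motion_profile(settings: MotionSettings) -> MotionProfile:
    """Build the periodic tilt trajectory for the given device settings.

    Amplitude is exactly ``max_angle_deg`` and ``|theta_dot|`` never
    exceeds ``max_speed_deg_s`` (both converted to radians internally).
    """
    alpha = math.radians(settings.max_angle_deg)
    omega = math.radians(settings.max_speed_deg_s)
    if settings.max_accel_deg_s2 is None:
        period, th, thd, thdd = _triangle_profile(alpha, omega)
    else:
        accel = math.radians(settings.max_accel_deg_s2)
        period, th, thd, thdd = _piecewise_profile(alpha, omega, accel)
    return MotionProfile(period=period, theta=th, theta_dot=thd, theta_ddot=thdd,
                         settings=settings)


def rocking_speed_to_rpm(speed_deg_s: float, max_angle_deg: float) -> float:
    """Convert a rocking speed (deg/s) to full cycles per minute (RPM).

    One cycle sweeps ``4*alpha`` degrees, so ``rpm = speed*60/(4*alpha)``.
    At alpha = 7 deg the conversion factor is 60/(4*7) = 2.143.
    """
    if max_angle_deg <= 0:
        raise ValueError("max rocking angle must be positive")
    return speed_deg_s * 60.0 / (4.0 * max_angle_deg)


def resonance_velocity(speed_deg_s: float, length: float, max_angle_deg: float) -> float:
    """Wavefront velocity (m/s) at which the surge resonates with the rocking.

    ``nu = omega*L/(2*alpha)``: the wavefront must traverse half the
    channel in the time the tilt sweeps from one extreme to the other,
    so that it returns in phase with the reversal.  omega and alpha
    enter as a ratio, so degree units cancel.
    """
    if max_angle_deg <= 0:
        raise ValueError("max rocking angle must be positive")
    if length <= 0:
        raise ValueError("channel length must be positive")
    return speed_deg_s * length / (2.0 * max_angle_deg)


def predicted_resonant_speed(
    max_angle_deg: float, mean_depth: float, length: float, gravity: float = 9.81
) -> float:
    """Rocking speed (deg/s) whose resonance velocity equals sqrt(g*h).

    Inverts ``nu = omega*L/(2*alpha)`` with the shallow-water gravity
    wave speed ``sqrt(g*h_mean)`` as the wavefront velocity.
    """
    if max_angle_deg <= 0 or mean_depth <= 0 or length <= 0:
        raise ValueError("angle, depth and length must be positive")
    return 2.0 * max_angle_deg * math.sqrt(gravity * mean_depth) / length
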