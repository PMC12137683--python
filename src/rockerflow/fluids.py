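"""Fluid properties: liquid-water density and viscosity correlations.

Density follows the Kell (1975) polynomial fit for air-free water at
atmospheric pressure; dynamic viscosity follows the Vogel-type equation
``mu = A * 10**(B / (T_K - C))`` with the classic parameters
A = 2.414e-5 Pa s, B = 247.8 K, C = 140 K.  Both are accurate to well
under 1% across 0-100 C, which is ample for shear-stress estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FluidProperties", "water_properties", "water_density", "water_viscosity"]

STANDARD_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class FluidProperties:
    """Density, viscosity and gravity bundled for the flow models."""

    density: float  # kg/m^3
    viscosity: float  # dynamic viscosity, Pa s
    temperature: float | None = None  # C, informational
    gravity: float = STANDARD_GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu/rho (m^2/s)."""
        return self.viscosity / self.density


def water_density(temperature_c: float) -> float:
    """Density of liquid water (kg/m^3) at ``temperature_c`` C (Kell 1975)."""
    t = temperature_c
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.897850e-3 * t)


def water_viscosity(temperature_c: float) -> float:
    """Dynamic viscosity of liquid water (Pa s) at ``temperature_c`` C."""
    t_k = temperature_c + 273.15
    return 2.414e-5 * 10.0 ** (247.8 / (t_k - 140.0))


def water_properties(temperature_c: float, gravity: float = STANDARD_GRAVITY) -> FluidProperties:
    """Water properties at a given temperature in the liquid range (0, 100) C.

    Examples
    --------
    >>> fluid = water_properties(37.0)
    >>> round(fluid.density)
    993
    >>> 6.7e-4 < fluid.viscosity < 7.1e-4
    True
    """
    if not (0.0 < temperature_c < 100.0):
        raise ValueError(
            f"temperature {temperature_c!r} C outside the liquid range (0, 100) C"
        )
    return FluidProperties(
        density=water_density(temperature_c),
        viscosity=water_viscosity(temperature_c),
        temperature=temperature_c,
        gravity=gravity,
    )
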