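"""Laminar pipe-flow equivalence: translating rocker shear to pipes.

Steady laminar (Poiseuille) flow in a circular pipe of radius R with
volumetric rate Q exerts a wall shear stress

    tau = 4 mu Q / (pi R^3) = 4 mu U_mean / R,

with ``Q = pi R^2 U_mean``.  The equivalence map evaluates tau over a
grid of bulk velocities and diameters and masks cells the rocker cannot
reproduce (tau outside its achievable range) or where pipe flow is no
longer laminar (Re > 2100).  Built-in scenarios cover the flow regimes
where biofilm growth is commonly problematic: urethral and venous
catheters, hemodialysis lines and household drinking-water pipes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fluids import FluidProperties
from .shear import ShearMap
from . import units

__all__ = [
    "PipeScenario",
    "EquivalenceGrid",
    "pipe_wall_shear",
    "bulk_velocity",
    "reynolds",
    "equivalence_grid",
    "builtin_scenarios",
    "LAMINAR_REYNOLDS_LIMIT",
]

LAMINAR_REYNOLDS_LIMIT = 2100.0


@dataclass(frozen=True)
class PipeScenario:
    """A real-world pipe-flow regime relevant to biofilm growth."""

    label: str
    description: str
    diameters_m: tuple  # representative inner diameters
    flow_rates_m3_s: tuple | None = None  # (min, max) volumetric rate
    velocities_m_s: tuple | None = None  # literature-quoted bulk velocities
    source: str = ""

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters_m):
            raise ValueError("pipe diameters must be positive")
        if self.flow_rates_m3_s and any(q < 0 for q in self.flow_rates_m3_s):
            raise ValueError("flow rates must be non-negative")
        if self.velocities_m_s and any(v < 0 for v in self.velocities_m_s):
            raise ValueError("velocities must be non-negative")

    def velocity_span(self) -> tuple:
        """(min, max) bulk velocity over diameters x flow rates (m/s)."""
        if self.velocities_m_s is not None:
            return (min(self.velocities_m_s), max(self.velocities_m_s))
        vels = [
            bulk_velocity(q, d / 2.0)
            for d in self.diameters_m
            for q in self.flow_rates_m3_s
        ]
        return (min(vels), max(vels))


@dataclass
class EquivalenceGrid:
    """tau(U, d) with a mask for unreachable or turbulent cells."""

    velocities_m_s: np.ndarray
    diameters_m: np.ndarray
    tau: np.ndarray  # shape (n_diameters, n_velocities)
    reynolds: np.ndarray
    masked: np.ndarray  # bool, same shape
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        D, U = np.meshgrid(self.diameters_m, self.velocities_m_s, indexing="ij")
        return pd.DataFrame(
            {
                "U_m_s": U.ravel(),
                "d_m": D.ravel(),
                "tau_Pa": self.tau.ravel(),
                "reynolds": self.reynolds.ravel(),
                "masked": self.masked.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def pipe_wall_shear(Q: float, R: float, mu: float) -> float:
    """Laminar wall shear stress tau = 4*mu*Q/(pi*R^3) (N/m^2)."""
    if R <= 0:
        raise ValueError("pipe radius must be positive")
    if Q < 0:
        raise ValueError("flow rate must be non-negative")
    return 4.0 * mu * Q / (np.pi * R**3)


def bulk_velocity(Q: float, R: float) -> float:
    """Mean velocity U = Q/(pi*R^2) (m/s)."""
    if R <= 0:
        raise ValueError("pipe radius must be positive")
    return Q / (np.pi * R**2)


def reynolds(U: float, d: float, fluid: FluidProperties) -> tuple[float, bool]:
    """Pipe Reynolds number rho*U*d/mu and a laminar flag (Re <= 2100)."""
    if d <= 0:
        raise ValueError("pipe diameter must be positive")
    re = fluid.density * U * d / fluid.viscosity
    return float(re), bool(re <= LAMINAR_REYNOLDS_LIMIT)


def equivalence_grid(
    fluid: FluidProperties,
    velocities_m_s: Sequence[float],
    diameters_m: Sequence[float],
    shear_map: ShearMap,
    basis: str = "peak",
    reynolds_limit: float = LAMINAR_REYNOLDS_LIMIT,
) -> EquivalenceGrid:
    """Pipe wall shear tau(U, d) masked to what the rocker can mimic.

    A cell is masked when the flow is turbulent (Re > ``reynolds_limit``)
    or when its tau falls outside the [min, max] of the shear map's
    ``basis`` matrix ("peak", the most permissive, or "avg").
    """
    if shear_map is None:
        raise ValueError("a shear map is required")
    mat = shear_map.peak if basis == "peak" else shear_map.avg
    if mat.size == 0 or np.all(np.isnan(mat)):
        raise ValueError("shear map is empty")
    lo = float(np.nanmin(mat))
    hi = float(np.nanmax(mat))

    U = np.asarray(list(velocities_m_s), dtype=float)
    d = np.asarray(list(diameters_m), dtype=float)
    if np.any(d <= 0):
        raise ValueError("pipe diameters must be positive")
    Dg, Ug = np.meshgrid(d, U, indexing="ij")
    tau = 8.0 * fluid.viscosity * Ug / Dg  # = 4 mu U / R
    re = fluid.density * Ug * Dg / fluid.viscosity
    masked = (re > reynolds_limit) | (tau < lo) | (tau > hi)
    return EquivalenceGrid(
        velocities_m_s=U,
        diameters_m=d,
        tau=tau,
        reynolds=re,
        masked=masked,
        meta={"basis": basis, "tau_range_Pa": [lo, hi], "reynolds_limit": reynolds_limit},
    )


def builtin_scenarios(household_rate: str = "per_minute") -> list[PipeScenario]:
    """The four preconfigured real-world scenarios (regions I-IV).

    ``household_rate`` selects how the drinking-water scenario flow is
    interpreted: ``"per_minute"`` (1 L/min, the default, consistent with
    household bulk velocities of a few cm/s to ~20 cm/s) or
    ``"per_second"`` (1 L/s, which would put even household pipes deep
    into the turbulent regime).
    """
    q_hemo = (units.ml_per_min_to_m3_s(200.0), units.ml_per_min_to_m3_s(400.0))
    if household_rate == "per_minute":
        q_house = (units.ml_per_min_to_m3_s(1000.0),) * 2
    elif household_rate == "per_second":
        q_house = (1e-3, 1e-3)
    else:
        raise ValueError("household_rate must be 'per_minute' or 'per_second'")
    return [
        PipeScenario(
            label="I",
            description="urethral catheters, 12 and 18 Fr, low to high bladder pressure",
            diameters_m=(
                units.french_to_diameter_m(12.0),
                units.french_to_diameter_m(18.0),
            ),
            velocities_m_s=(0.08, 0.15, 0.35, 0.60),
            source="literature-quoted velocity ranges (8-35 and 15-60 cm/s)",
        ),
        PipeScenario(
            label="II",
            description="venous catheters, 16 and 24 G, infusion heights 10-100 cm",
            diameters_m=(
                units.gauge_to_inner_diameter_m(16),
                units.gauge_to_inner_diameter_m(24),
            ),
            velocities_m_s=(0.017, 0.042, 1.3, 2.0),
            source="literature-quoted velocity ranges (1.7-130 and 4.2-200 cm/s)",
        ),
        PipeScenario(
            label="III",
            description="hemodialysis bloodlines (5 mm) and pump tubing (9 mm), 200-400 mL/min",
            diameters_m=(5e-3, 9e-3),
            flow_rates_m3_s=q_hemo,
            source="computed from flow rate via U = Q/(pi R^2)",
        ),
        PipeScenario(
            label="IV",
            description="household drinking-water pipes, 1.0-2.5 cm",
            diameters_m=(0.010, 0.025),
            flow_rates_m3_s=q_house,
            source=f"computed from 1 L {household_rate.replace('per_', 'per ')}",
        ),
    ]
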