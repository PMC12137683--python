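"""Reduction of shear records into maps, peaks, exceedance and forces.

The headline product is the shear map: one simulated rocking speed per
row, the period-averaged |tau| along the channel per column, giving a
quick translation between front-panel speed settings and the wall shear
stress a biofilm experiences.  Averages use |tau| because a signed
average cancels by the back-and-forth symmetry of the flow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .fluids import FluidProperties
from .geometry import WellGeometry
from .motion import MotionProfile, MotionSettings, make_motion_profile
from .solver import ShearRecord, SolverConfig, SolverError, simulate

__all__ = [
    "ShearMap",
    "ResonanceResult",
    "period_average",
    "peak_and_exceedance",
    "speed_sweep",
    "find_resonant_speed",
    "force_on_cell",
    "DEFAULT_CELL_AREA_M2",
]

#: Effective bed area of a single bacterial cell used to convert wall
#: shear stress into a per-cell drag force.  33.3 um^2 corresponds to a
#: rod-shaped bacillus footprint of roughly 1.1 x 30 um^2 equivalent
#: drag area and maps 0.46 N/m^2 -> 15 pN and 2.4 N/m^2 -> 80 pN.
DEFAULT_CELL_AREA_M2 = 33.3e-12


@dataclass
class ShearMap:
    """Period-averaged and peak |tau| versus rocking speed and position."""

    speeds_deg_s: np.ndarray  # rows, ascending
    x: np.ndarray  # columns (m)
    avg: np.ndarray  # period-averaged |tau| (n_speeds, n_x)
    peak: np.ndarray  # peak |tau| (n_speeds, n_x)
    fill_volume_ml: float
    max_angle_deg: float
    mask: np.ndarray | None = None  # True where a run failed
    meta: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    @property
    def max_avg(self) -> float:
        return float(np.nanmax(self.avg))

    @property
    def max_peak(self) -> float:
        return float(np.nanmax(self.peak))

    def to_csv(self, prefix) -> None:
        """Write <prefix>_avg.csv, <prefix>_peak.csv and <prefix>_meta.json."""
        import pandas as pd

        cols = [f"x_{xi:.6f}_m" for xi in self.x]
        for name, mat in (("avg", self.avg), ("peak", self.peak)):
            df = pd.DataFrame(mat, columns=cols)
            df.insert(0, "speed_deg_s", self.speeds_deg_s)
            df.to_csv(f"{prefix}_{name}.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {
                    "fill_volume_ml": self.fill_volume_ml,
                    "max_angle_deg": self.max_angle_deg,
                    **self.meta,
                },
                fh,
                indent=2,
            )


class ResonanceResult(NamedTuple):
    speed_deg_s: float
    interior: bool  # False when the peak sits on the sweep boundary


def period_average(rec: ShearRecord, profile: MotionProfile) -> np.ndarray:
    """Per-position time-mean of |tau| over exactly the last full period.

    Raises
    ------
    ValueError
        If the record covers less than one rocking period.
    """
    T = profile.period
    t = rec.times
    if t.size < 2:
        raise ValueError("record too short to average")
    dt = rec.sample_interval
    span = t[-1] - t[0]
    if span + dt < T * (1 - 1e-9):
        raise ValueError(
            f"record spans {span + dt:.4g} s, shorter than one period {T:.4g} s"
        )
    n_per = int(round(T / dt))
    window = np.abs(rec.tau[-n_per:])
    return window.mean(axis=0)


def peak_and_exceedance(
    rec: ShearRecord, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position peak |tau| and longest contiguous time above threshold.

    Durations are measured on the record's sampling grid (default 1 kHz):
    a run of k consecutive samples above the threshold counts as k*dt.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    abs_tau = np.abs(rec.tau)
    peak = abs_tau.max(axis=0)
    dt = rec.sample_interval
    above = abs_tau > threshold
    nt, nx = above.shape
    longest = np.zeros(nx)
    run = np.zeros(nx)
    for k in range(nt):
        run = np.where(above[k], run + 1, 0.0)
        longest = np.maximum(longest, run)
    return peak, longest * dt


def speed_sweep(
    geom: WellGeometry,
    fill_volume: float,
    speeds_deg_s: Sequence[float],
    max_angle_deg: float,
    fluid: FluidProperties,
    cfg: SolverConfig | None = None,
    max_accel_deg_s2: float | None = None,
) -> ShearMap:
    """Run one simulation per rocking speed and stack the reductions.

    Failed runs are reported in ``ShearMap.failures`` and masked (NaN
    rows) rather than aborting the whole sweep.
    """
    cfg = cfg or SolverConfig()
    speeds = np.sort(np.asarray(list(speeds_deg_s), dtype=float))
    if speeds.size == 0:
        raise ValueError("at least one speed required")
    n = cfg.n_cells
    avg = np.full((speeds.size, n), np.nan)
    peak = np.full((speeds.size, n), np.nan)
    mask = np.zeros(speeds.size, dtype=bool)
    failures: dict = {}
    x = None
    for i, w in enumerate(speeds):
        # Simulation sweeps may probe slightly beyond the front-panel
        # speed range (the hardware stops at 99 deg/s).
        settings = MotionSettings(
            max_angle_deg, float(w), max_accel_deg_s2, enforce_limits=False
        )
        profile = make_motion_profile(settings)
        try:
            rec = simulate(geom, fill_volume, profile, fluid, cfg)
        except SolverError as err:
            mask[i] = True
            failures[float(w)] = str(err)
            continue
        x = rec.x
        avg[i] = period_average(rec, profile)
        peak[i] = np.abs(rec.tau).max(axis=0)
    if x is None:
        raise SolverError("every run in the sweep failed: " + repr(failures))
    return ShearMap(
        speeds_deg_s=speeds,
        x=x,
        avg=avg,
        peak=peak,
        fill_volume_ml=fill_volume * 1e6,
        max_angle_deg=max_angle_deg,
        mask=mask if mask.any() else None,
        meta={"n_cells": cfg.n_cells, "spinup_periods": cfg.spinup_periods},
        failures=failures,
    )


def find_resonant_speed(shear_map: ShearMap, basis: str = "peak") -> ResonanceResult:
    """Rocking speed whose row attains the global maximum shear.

    Ties break toward the lower speed.  When the maximum sits at either
    end of the sweep there is no interior resonance and the result is
    flagged accordingly.
    """
    if shear_map.speeds_deg_s.size < 3:
        raise ValueError("need at least 3 speeds to locate a resonance")
    mat = shear_map.peak if basis == "peak" else shear_map.avg
    row_max = np.nanmax(mat, axis=1)
    i = int(np.nanargmax(row_max))  # argmax returns the first (lowest) speed on ties
    interior = 0 < i < shear_map.speeds_deg_s.size - 1
    return ResonanceResult(float(shear_map.speeds_deg_s[i]), interior)


def force_on_cell(tau: float, effective_area: float = DEFAULT_CELL_AREA_M2) -> float:
    """Drag force (N) on one surface-attached cell: F = tau * area."""
    if effective_area <= 0:
        raise ValueError("effective area must be positive")
    return tau * effective_area
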