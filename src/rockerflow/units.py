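"""Unit conversions between front-panel / clinical units and SI."""

from __future__ import annotations

__all__ = [
    "ml_to_m3",
    "m3_to_ml",
    "ml_per_min_to_m3_s",
    "french_to_diameter_m",
    "gauge_to_inner_diameter_m",
    "GAUGE_INNER_DIAMETER_MM",
]


def ml_to_m3(ml: float) -> float:
    return ml * 1e-6


def m3_to_ml(m3: float) -> float:
    return m3 * 1e6


def ml_per_min_to_m3_s(ml_per_min: float) -> float:
    return ml_per_min * 1e-6 / 60.0


def french_to_diameter_m(fr: float) -> float:
    """Catheter French size to diameter: 1 Fr = 1/3 mm."""
    if fr <= 0:
        raise ValueError("French size must be positive")
    return fr / 3.0 * 1e-3


#: Birmingham (hypodermic) gauge to regular-wall inner diameter, mm.
#: Values from the ISO 9626 regular-wall needle tubing table.
GAUGE_INNER_DIAMETER_MM = {
    14: 1.600,
    16: 1.194,
    18: 0.838,
    20: 0.603,
    22: 0.413,
    24: 0.311,
    26: 0.260,
}


def gauge_to_inner_diameter_m(gauge: int) -> float:
    """Needle/catheter gauge to inner diameter (m) via a fixed lookup."""
    try:
        return GAUGE_INNER_DIAMETER_MM[int(gauge)] * 1e-3
    except KeyError:
        raise ValueError(
            f"gauge {gauge!r} not in lookup table {sorted(GAUGE_INNER_DIAMETER_MM)}"
        ) from None
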