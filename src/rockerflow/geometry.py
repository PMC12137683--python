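"""Well geometry of a rectangular rocking-channel culture plate.

The growth channel is modelled as a flat-bottomed rectangular well of
length ``L`` along the rocking direction and width ``W`` across it, so
volume and fill depth convert through the floor area ``L*W``.  The tilt
pivot sits at the channel mid-point (the "CoC", centre of channel) at
floor level; positions ``x`` are measured from the CoC, positive toward
the end that dips down for positive tilt angles.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WellGeometry", "fill_depth"]


@dataclass(frozen=True)
class WellGeometry:
    """Dimensions of one culture-plate well.

    Parameters
    ----------
    length : float
        Channel length L along the rocking direction (m).
    width : float
        Channel width W (m).  Default matches a well sized for a
        26 x 76 mm microscope slide.
    capacity : float
        Maximum fill volume (m^3).
    pivot_x : float
        Position of the tilt axis relative to the channel centre (m).
    max_depth : float
        Maximum water depth the well can hold (m); ``fill_depth`` at
        full capacity must not exceed it.
    """

    length: float = 0.08
    width: float = 0.026
    capacity: float = 24e-6
    pivot_x: float = 0.0
    max_depth: float = 0.0145

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("channel length and width must be positive")
        if self.capacity <= 0:
            raise ValueError("well capacity must be positive")
        if self.max_depth <= 0:
            raise ValueError("max well depth must be positive")
        if self.capacity / (self.length * self.width) > self.max_depth * (1 + 1e-12):
            raise ValueError(
                "well capacity exceeds the volume held at the maximum depth"
            )

    @property
    def floor_area(self) -> float:
        """Channel floor area L*W (m^2)."""
        return self.length * self.width

    def volume_at_depth(self, depth: float) -> float:
        """Volume (m^3) of a level fill of the given depth (m)."""
        if depth < 0:
            raise ValueError(f"depth must be non-negative, got {depth!r}")
        return self.floor_area * depth

    def fill_depth(self, volume: float) -> float:
        """Level water depth (m) for a given fill volume (m^3).

        Inverse of :meth:`volume_at_depth`; rejects volumes outside
        ``[0, capacity]``.
        """
        return fill_depth(volume, self)


def fill_depth(volume: float, geom: WellGeometry) -> float:
    """Depth (m) of ``volume`` m^3 of liquid in a flat-bottomed well.

    Raises
    ------
    ValueError
        If the volume is negative or exceeds the well capacity.
    """
    if volume < 0:
        raise ValueError(f"fill volume must be non-negative, got {volume!r} m^3")
    if volume > geom.capacity * (1 + 1e-12):
        raise ValueError(
            f"fill volume {volume!r} m^3 exceeds well capacity {geom.capacity!r} m^3"
        )
    return volume / geom.floor_area
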