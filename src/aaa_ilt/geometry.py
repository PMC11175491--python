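"""Parametric AAA cross-section geometry.

The idealized slice is a circular vessel wall (outer radius ``b``, thickness
``t``) whose cavity of radius ``a = b - t`` is filled by an annular
intraluminal thrombus surrounding a circular lumen.  The lumen may be
concentric with the vessel or shifted by a fixed offset toward/away from the
spine or laterally, which makes the thrombus eccentric in thickness.  The
thrombus fraction is the share of the cavity cross-section occupied by clot,

    f = 1 - (r_lumen / a)**2,

so ``f = 0`` is a thrombus-free vessel and ``f -> 1`` a near-occluded one.
An optional rigid circular spine sits tangent to the outer wall on the
posterior side.

All lengths are millimetres; anterior is +y, posterior (spine side) -y,
left -x, right +x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContainmentError, DegenerateProbeError, GeometryError

__all__ = [
    "POSITIONS",
    "SliceGeometry",
    "ProbeSet",
    "geometry_from_fraction",
    "probe_points",
]

#: Canonical lumen positions; magnitudes of the offset are configurable.
POSITIONS = ("center", "anterior", "posterior_spine", "left", "right")

_POSITION_DIRECTIONS = {
    "center": np.array([0.0, 0.0]),
    "anterior": np.array([0.0, 1.0]),
    "posterior_spine": np.array([0.0, -1.0]),
    "left": np.array([-1.0, 0.0]),
    "right": np.array([1.0, 0.0]),
}

_CONTAINMENT_TOL = 1e-12


@dataclass(frozen=True)
class SliceGeometry:
    """Idealized AAA slice: wall annulus + eccentric lumen + optional spine.

    Parameters
    ----------
    wall_outer_radius, wall_thickness
        Outer radius ``b`` and thickness ``t`` of the vessel wall, mm.
    lumen_radius
        Radius of the circular lumen, mm.
    lumen_offset
        2-vector from the vessel centre to the lumen centre, mm.
    spine_radius, spine_gap
        Radius of the rigid spine circle and its standoff from the outer
        wall (0 = tangent on the posterior side).
    """

    wall_outer_radius: float = 25.0
    wall_thickness: float = 2.0
    lumen_radius: float = 23.0
    lumen_offset: tuple[float, float] = (0.0, 0.0)
    spine_radius: float = 15.0
    spine_gap: float = 0.0

    def __post_init__(self):
        if self.wall_thickness <= 0 or self.wall_outer_radius <= 0:
            raise GeometryError("wall radii must be positive")
        if self.wall_inner_radius <= 0:
            raise GeometryError("wall thickness exceeds outer radius")
        if self.lumen_radius <= 0:
            raise GeometryError("lumen radius must be positive")
        off = self.offset_magnitude
        if off + self.lumen_radius >= self.wall_inner_radius + _CONTAINMENT_TOL:
            if not (off == 0.0 and self.lumen_radius == self.wall_inner_radius):
                raise ContainmentError(
                    f"lumen (|offset|={off:g} + r={self.lumen_radius:g} mm) does "
                    f"not fit inside the cavity (r={self.wall_inner_radius:g} mm)"
                )
        if self.spine_radius < 0 or self.spine_gap < 0:
            raise GeometryError("spine radius/gap must be non-negative")
        object.__setattr__(self, "lumen_offset", tuple(float(v) for v in self.lumen_offset))

    @property
    def wall_inner_radius(self) -> float:
        return self.wall_outer_radius - self.wall_thickness

    @property
    def offset_magnitude(self) -> float:
        return math.hypot(*self.lumen_offset)

    @property
    def thrombus_fraction(self) -> float:
        """Area share of the cavity occupied by thrombus."""
        return 1.0 - (self.lumen_radius / self.wall_inner_radius) ** 2

    @property
    def has_thrombus(self) -> bool:
        return self.lumen_radius < self.wall_inner_radius

    @property
    def lumen_center(self) -> np.ndarray:
        return np.asarray(self.lumen_offset, dtype=float)

    @property
    def spine_center(self) -> np.ndarray:
        """Centre of the rigid spine circle (posterior of the vessel)."""
        return np.array(
            [0.0, -(self.wall_outer_radius + self.spine_gap + self.spine_radius)]
        )


def geometry_from_fraction(
    fraction: float,
    position: str = "center",
    offset_magnitude: float = 2.5,
    *,
    wall_outer_radius: float = 25.0,
    wall_thickness: float = 2.0,
    spine_radius: float = 15.0,
    spine_gap: float = 0.0,
) -> SliceGeometry:
    """Build the slice geometry realizing a requested thrombus fraction.

    The lumen radius follows from the fraction, ``r = a*sqrt(1 - f)``, and the
    lumen centre is shifted by ``offset_magnitude`` in the direction named by
    ``position`` ('center' means no offset).

    Raises
    ------
    ContainmentError
        If the offset lumen would touch or cross the cavity boundary.
    """
    if not 0.0 <= fraction < 1.0:
        raise GeometryError(f"fraction must be in [0, 1), got {fraction}")
    if position not in _POSITION_DIRECTIONS:
        raise GeometryError(f"unknown position {position!r}; expected one of {POSITIONS}")
    a = wall_outer_radius - wall_thickness
    lumen_radius = a * math.sqrt(1.0 - fraction)
    direction = _POSITION_DIRECTIONS[position]
    offset = direction * (0.0 if position == "center" else offset_magnitude)
    return SliceGeometry(
        wall_outer_radius=wall_outer_radius,
        wall_thickness=wall_thickness,
        lumen_radius=lumen_radius,
        lumen_offset=tuple(offset),
        spine_radius=spine_radius,
        spine_gap=spine_gap,
    )


@dataclass(frozen=True)
class ProbeSet:
    """16 measurement points: 8 on the outer wall, 8 on the lumen lining.

    Four cutting lines through the lumen centroid at 45 deg increments; each
    line meets the outer wall twice and the lumen lining twice.  ``labels``
    are ``("wall"|"lining", line_angle_deg, end)`` with ``end`` +1/-1 for the
    two ray directions.
    """

    points: np.ndarray  # (16, 2) mm
    labels: tuple = field(default=())

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (16, 2):
            raise GeometryError(f"expected 16 probe points, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)

    @property
    def wall_points(self) -> np.ndarray:
        return self.points[:8]

    @property
    def lining_points(self) -> np.ndarray:
        return self.points[8:]


def probe_points(geometry: SliceGeometry) -> ProbeSet:
    """Locate the 16 probe points of the measurement scheme.

    Lines are anchored at the lumen centroid: at high fraction with an offset
    lumen the vessel centre can lie outside the lumen entirely, so
    vessel-centred lines would miss the lining.
    """
    c = geometry.lumen_center
    b = geometry.wall_outer_radius
    r_l = geometry.lumen_radius
    wall_pts, lining_pts, wall_labels, lining_labels = [], [], [], []
    for ang_deg in (0, 45, 90, 135):
        ang = math.radians(ang_deg)
        d = np.array([math.cos(ang), math.sin(ang)])
        for sign in (+1, -1):
            # ray c + t*sign*d meets the outer circle |x| = b at
            # t = -sign*(c.d) + sqrt((c.d)^2 + b^2 - |c|^2)
            cd = float(c @ d) * sign
            disc = cd * cd + b * b - float(c @ c)
            if disc <= 0:
                raise DegenerateProbeError(
                    f"probe line at {ang_deg} deg misses the outer wall"
                )
            t = -cd + math.sqrt(disc)
            wall_pts.append(c + t * sign * d)
            wall_labels.append(("wall", ang_deg, sign))
            lining_pts.append(c + r_l * sign * d)
            lining_labels.append(("lining", ang_deg, sign))
    return ProbeSet(
        points=np.vstack([wall_pts, lining_pts]),
        labels=tuple(wall_labels + lining_labels),
    )
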