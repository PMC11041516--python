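"""Sensor placement geometry: boresight, field-of-view membership, coverage.

Coordinate frame: origin at the centre of the toilet seat on the seat plane;
x points forward (toward the stall door, the direction the seated person
faces), y points left across the stall, z points up. All lengths are metres
internally; placement fields are centimetres to match how mounting distances
are normally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DevicePlacement:
    """Mounting of the sensor relative to the seat.

    ``forward_offset`` is the horizontal distance from the seat-centre chest
    plane; ``yaw_angle`` is the device-internal mount angle out from the wall
    (descriptive of the physical mount — the boresight below already points
    from the sensor toward the seat axis).
    """

    forward_offset: float = 85.0  # cm
    height_above_seat: float = 85.0  # cm
    depression_angle: float = 30.0  # degrees below horizontal
    yaw_angle: float = 45.0  # degrees out from the mounting wall

    def validate(self) -> None:
        if self.forward_offset <= 0:
            raise ValueError("forward_offset must be positive")
        if not 0 <= self.depression_angle < 90:
            raise ValueError("depression_angle must be in [0, 90)")

    @property
    def position(self) -> np.ndarray:
        """Sensor position in metres."""
        return np.array([self.forward_offset / 100.0, 0.0,
                         self.height_above_seat / 100.0])

    @property
    def boresight_direction(self) -> np.ndarray:
        """Unit vector along the sensor's central axis."""
        d = math.radians(self.depression_angle)
        return np.array([-math.cos(d), 0.0, -math.sin(d)])


@dataclass(frozen=True)
class FovSpec:
    horizontal: float = 65.0  # degrees, full angle
    vertical: float = 53.0

    def validate(self) -> None:
        if not (0 < self.horizontal < 180 and 0 < self.vertical < 180):
            raise ValueError("field-of-view angles must be in (0, 180)")


@dataclass(frozen=True)
class StallGeometry:
    """Public-restroom stall envelope per building standards."""

    width: float = 915.0  # mm (standard range 890-940)
    length: float = 1500.0  # mm
    door_opening: float = 860.0  # mm
    seat_height_reference: float = 43.0  # cm above floor

    def validate(self) -> None:
        if min(self.width, self.length, self.door_opening) <= 0:
            raise ValueError("stall dimensions must be positive")


@dataclass(frozen=True)
class TargetCoverage:
    label: str
    point: tuple[float, float, float]
    in_fov: bool
    range_m: float
    horizontal_off_axis: float
    vertical_off_axis: float


@dataclass(frozen=True)
class CoverageReport:
    targets: tuple[TargetCoverage, ...]

    @property
    def fraction_covered(self) -> float:
        if not self.targets:
            return 0.0
        return sum(tc.in_fov for tc in self.targets) / len(self.targets)

    def to_dict(self) -> dict:
        return {
            "fraction_covered": self.fraction_covered,
            "targets": [
                {
                    "label": tc.label,
                    "point_m": list(tc.point),
                    "in_fov": tc.in_fov,
                    "range_m": tc.range_m,
                    "horizontal_off_axis_deg": tc.horizontal_off_axis,
                    "vertical_off_axis_deg": tc.vertical_off_axis,
                }
                for tc in self.targets
            ],
        }


def off_axis_angles(
    sensor_position: np.ndarray,
    boresight_dir: np.ndarray,
    point: np.ndarray,
) -> tuple[float, float, float, float]:
    """(horizontal, vertical) off-axis angles in degrees, range, forward component.

    The sensor frame is built from the boresight and the world vertical, so
    the horizontal angle is measured in the sensor's azimuth plane and the
    vertical angle in its elevation plane.
    """
    f = np.asarray(boresight_dir, dtype=float)
    f = f / np.linalg.norm(f)
    up = np.array([0.0, 0.0, 1.0])
    r = np.cross(f, up)
    if np.linalg.norm(r) < 1e-12:  # boresight straight up/down: pick any right
        r = np.array([0.0, 1.0, 0.0])
    r = r / np.linalg.norm(r)
    u = np.cross(r, f)
    v = np.asarray(point, dtype=float) - np.asarray(sensor_position, dtype=float)
    x = float(np.dot(v, f))
    y = float(np.dot(v, r))
    z = float(np.dot(v, u))
    rng = float(np.linalg.norm(v))
    h = math.degrees(math.atan2(abs(y), x)) if (x, y) != (0.0, 0.0) else 0.0
    vv = math.degrees(math.atan2(abs(z), x)) if (x, z) != (0.0, 0.0) else 0.0
    return h, vv, rng, x


def boresight(
    placement: DevicePlacement = DevicePlacement(),
) -> tuple[np.ndarray, float]:
    """Boresight intersection with the seat-centre chest plane (x = 0).

    Returns ``(aim_point, range_m)``: where the central axis crosses the
    vertical plane through the seat centre, and the straight-line distance to
    it. At the published mounting this lands ~35 cm above the seat at a range
    that rounds to 1 m.
    """
    placement.validate()
    pos = placement.position
    d = placement.boresight_direction
    if abs(d[0]) < 1e-12:
        raise ValueError("boresight is parallel to the chest plane")
    s = -pos[0] / d[0]
    aim = pos + s * d
    return aim, float(s)


def slant_range(
    placement: DevicePlacement,
    target_height_cm: float = 35.0,
) -> float:
    """Euclidean distance (m) from the sensor to a point on the seat axis."""
    placement.validate()
    target = np.array([0.0, 0.0, target_height_cm / 100.0])
    return float(np.linalg.norm(target - placement.position))


def required_depression(
    placement: DevicePlacement,
    target_height_cm: float = 35.0,
) -> float:
    """Depression angle (degrees) aiming the sensor at a seat-axis point."""
    placement.validate()
    dz = placement.height_above_seat - target_height_cm
    return math.degrees(math.atan2(dz, placement.forward_offset))


def in_fov(
    placement: DevicePlacement,
    point,
    fov: FovSpec = FovSpec(),
) -> bool:
    """True iff the point lies inside the forward field-of-view cone."""
    fov.validate()
    h, v, _rng, x = off_axis_angles(
        placement.position, placement.boresight_direction, np.asarray(point, float)
    )
    if x <= 0:
        return False
    return h <= fov.horizontal / 2.0 and v <= fov.vertical / 2.0


def default_targets() -> dict[str, tuple[float, float, float]]:
    """Modelled chest positions (m) for the five on-seat postures."""
    return {
        "upright": (0.0, 0.0, 0.35),
        "slump_forward": (0.30, 0.0, 0.35),
        "slump_backward": (-0.10, 0.0, 0.55),
        "slump_left": (0.0, 0.25, 0.35),
        "slump_right": (0.0, -0.25, 0.35),
    }


def coverage_report(
    stall: StallGeometry = StallGeometry(),
    placement: DevicePlacement = DevicePlacement(),
    targets: dict[str, tuple[float, float, float]] | None = None,
    fov: FovSpec = FovSpec(),
) -> CoverageReport:
    """Field-of-view membership for each labelled target point."""
    stall.validate()
    placement.validate()
    fov.validate()
    if targets is None:
        targets = default_targets()
    if not targets:
        raise ValueError("targets must be non-empty")
    rows = []
    for label, point in targets.items():
        h, v, rng, x = off_axis_angles(
            placement.position, placement.boresight_direction, np.asarray(point, float)
        )
        covered = x > 0 and h <= fov.horizontal / 2 and v <= fov.vertical / 2
        rows.append(
            TargetCoverage(label, tuple(point), bool(covered), rng, h, v)
        )
    return CoverageReport(targets=tuple(rows))
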