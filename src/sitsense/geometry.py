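"""Skeleton joint-angle geometry.

Body-angle and gaze features from 3-D joint positions in a right-handed,
y-up camera frame measured in meters:

* lumbar angle  (alpha) — angle between the spine-base→neck segment and the
  vertical axis; a proxy for trunk lean,
* cervical angle (beta) — angle between the neck→head segment and the
  vertical axis; a proxy for neck flexion,
* sight angle   (gamma) — signed elevation of the gaze vector (head →
  screen point) relative to horizontal; negative = looking down,
* sight distance (delta) — Euclidean head-to-screen distance.

The head joint proxies the eye position (no eye joint is tracked).
Cosines are clipped to [−1, 1] before ``arccos`` to absorb floating-point
drift; degenerate (zero-length) segments raise
:class:`~sitsense.errors.InvalidGeometryError` rather than returning 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError

__all__ = [
    "CameraConventions",
    "SkeletonFrame",
    "ScreenPoint",
    "angle_to_vertical",
    "lumbar_angle",
    "cervical_angle",
    "sight_angle",
    "sight_distance",
    "lateral_angle",
    "kinect_to_camera",
]

_EPS = 1e-12


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise InvalidGeometryError(f"expected a 3-point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidGeometryError("non-finite coordinates")
    return a


@dataclass(frozen=True)
class CameraConventions:
    """Camera coordinate conventions: unit axes, meters, frame rate.

    Defaults are a right-handed y-up frame: vertical axis (0,1,0) and
    horizontal axis (1,0,0) pointing from the camera toward the screen side
    of the scene.
    """

    vertical_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    horizontal_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        ey = _as_point(self.vertical_axis)
        ex = _as_point(self.horizontal_axis)
        for name, v in (("vertical_axis", ey), ("horizontal_axis", ex)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise InvalidGeometryError(f"{name} must be unit-norm")
        if abs(float(ey @ ex)) > 1e-9:
            raise InvalidGeometryError("camera axes must be orthogonal")
        if not self.frame_rate > 0:
            raise InvalidGeometryError("frame_rate must be positive")

    @property
    def ey(self) -> np.ndarray:
        return np.asarray(self.vertical_axis, dtype=float)

    @property
    def ex(self) -> np.ndarray:
        return np.asarray(self.horizontal_axis, dtype=float)

    @property
    def lateral(self) -> np.ndarray:
        """Unit normal of the sagittal (ex, ey) plane."""
        return np.cross(self.ex, self.ey)


DEFAULT_CONVENTIONS = CameraConventions()


@dataclass(frozen=True)
class SkeletonFrame:
    """Timestamped 3-D positions of the three tracked joints of one person.

    Only spine-base, neck and head are used by the method; the coordinates
    are in meters in the camera frame.
    """

    frame_index: int
    spine_base: tuple[float, float, float]
    neck: tuple[float, float, float]
    head: tuple[float, float, float]
    person_id: int = 0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise InvalidGeometryError("frame_index must be non-negative")
        for j in ("spine_base", "neck", "head"):
            _as_point(getattr(self, j))

    def joint(self, name: str) -> np.ndarray:
        return _as_point(getattr(self, name))


@dataclass(frozen=True)
class ScreenPoint:
    """3-D reference point of the screen surface, meters."""

    position: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        _as_point(self.position)

    @property
    def point(self) -> np.ndarray:
        return _as_point(self.position)


def angle_to_vertical(p_from, p_to, conv: CameraConventions = DEFAULT_CONVENTIONS,
                      *, joints: tuple[str, str] = ("p_from", "p_to")) -> float:
    """Angle in [0, pi] between the segment p_from→p_to and the vertical axis.

    Raises :class:`InvalidGeometryError` naming the joints when the segment
    is degenerate.
    """
    v = _as_point(p_to) - _as_point(p_from)
    n = float(np.linalg.norm(v))
    if n < _EPS:
        raise InvalidGeometryError(
            f"degenerate segment {joints[0]}->{joints[1]}: zero length")
    c = float(v @ conv.ey) / n
    return float(math.acos(max(-1.0, min(1.0, c))))


def lumbar_angle(frame: SkeletonFrame,
                 conv: CameraConventions = DEFAULT_CONVENTIONS) -> float:
    """Trunk-lean angle alpha (radians): spine-base→neck vs vertical."""
    return angle_to_vertical(frame.spine_base, frame.neck, conv,
                             joints=("spine_base", "neck"))


def cervical_angle(frame: SkeletonFrame,
                   conv: CameraConventions = DEFAULT_CONVENTIONS) -> float:
    """Neck-flexion angle beta (radians): neck→head vs vertical."""
    return angle_to_vertical(frame.neck, frame.head, conv,
                             joints=("neck", "head"))


def sight_angle(head, screen: ScreenPoint,
                conv: CameraConventions = DEFAULT_CONVENTIONS) -> float:
    """Signed gaze elevation gamma (radians) of the head→screen vector.

    The magnitude is the angle between the gaze vector and the horizontal
    axis taken in the gaze's own vertical plane (i.e. the elevation angle);
    the sign is negative when the screen lies below eye level and
    non-negative otherwise.
    """
    gaze = screen.point - _as_point(head)
    n = float(np.linalg.norm(gaze))
    if n < _EPS:
        raise InvalidGeometryError("degenerate gaze: head coincides with screen")
    s = float(gaze @ conv.ey) / n
    return float(math.asin(max(-1.0, min(1.0, s))))


def sight_distance(head, screen: ScreenPoint) -> float:
    """Euclidean head-to-screen distance delta (meters)."""
    return float(np.linalg.norm(_as_point(head) - screen.point))


def lateral_angle(frame: SkeletonFrame,
                  conv: CameraConventions = DEFAULT_CONVENTIONS) -> float:
    """Out-of-sagittal-plane lean (radians, >= 0) of the spine segment.

    Angle between spine-base→neck and the vertical plane spanned by the
    camera's horizontal and vertical axes; used to detect sideways leaning,
    which the in-plane lumbar angle alone cannot distinguish.
    """
    v = frame.joint("neck") - frame.joint("spine_base")
    n = float(np.linalg.norm(v))
    if n < _EPS:
        raise InvalidGeometryError("degenerate segment spine_base->neck: zero length")
    s = abs(float(v @ conv.lateral)) / n
    return float(math.asin(max(0.0, min(1.0, s))))


def kinect_to_camera(p) -> tuple[float, float, float]:
    """Convert a Kinect SDK camera-space point to the package frame.

    Kinect camera space is right-handed, y-up, meters, with +x to the
    sensor's left and +z toward the scene. Rotating half a turn about the
    vertical axis gives this package's frame (+x to the camera's right,
    +z from the scene toward the camera) while preserving handedness:
    (x, y, z) -> (-x, y, -z).
    """
    x, y, z = _as_point(p)
    return (-float(x), float(y), -float(z))
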