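"""Quaternion and axis-angle algebra with the world-frame conventions used
throughout the package.

World frame
-----------
``x`` fore-aft (anterior positive), ``y`` vertical (up positive), ``z``
mediolateral (right positive).  Gravity is ``(0, -9.81, 0)`` m/s^2.  All
orientations are *sensor-to-world* (or segment-to-world) unless stated
otherwise: ``q.rotate(v_local)`` maps a vector expressed in the local frame
into world coordinates.

Quaternions are scalar-first ``(w, x, y, z)`` and kept unit-norm; ``q`` and
``-q`` denote the same rotation and are treated as equal everywhere.

Heading
-------
The *heading* of an orientation is the signed angle, about the world vertical
``+y`` (right-hand rule), between the horizontal projection of the rotated
forward axis (local ``+x``) and world ``+x``.  Without a magnetometer the
heading is unobservable, so calibration aligns headings across sensors;
``rotate_heading`` applies a pre-multiplied rotation about world ``+y``, the
unique correction that changes heading while leaving the gravity alignment
(inclination) of the orientation untouched.

Angles at this public interface are in degrees; radians appear only in
internal integration steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRAVITY",
    "UP",
    "FORWARD",
    "Quaternion",
    "AxisAngle",
    "DegenerateHeadingError",
    "heading_angle",
    "rotate_heading",
    "wrap_angle",
]

#: Gravitational acceleration in the world frame, m/s^2.
GRAVITY = np.array([0.0, -9.81, 0.0])
#: World vertical (up) unit vector.
UP = np.array([0.0, 1.0, 0.0])
#: Designated forward axis of a frame, used for heading extraction.
FORWARD = np.array([1.0, 0.0, 0.0])

_HEADING_EPS = 1e-6


class DegenerateHeadingError(ValueError):
    """Raised when the forward axis is vertical and heading is undefined."""


def wrap_angle(angle_deg: float) -> float:
    """Map an angle in degrees to the interval (-180, 180]."""
    a = math.fmod(angle_deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class AxisAngle:
    """Rotation as a unit axis and an angle in degrees in [0, 180].

    Zero angle represents the identity; its axis is arbitrary.
    """

    axis: np.ndarray
    angle: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if self.angle > 0.0:
            n = np.linalg.norm(axis)
            if n == 0.0:
                raise ValueError("axis must be non-zero for a non-zero angle")
            axis = axis / n
        object.__setattr__(self, "axis", axis)


class Quaternion:
    """Unit quaternion, scalar-first (w, x, y, z).

    Constructors normalize defensively, so the unit-norm invariant holds
    after every operation.  Comparison helpers treat ``q`` and ``-q`` as the
    same rotation.
    """

    __slots__ = ("_q",)

    def __init__(self, w: float, x: float, y: float, z: float):
        q = np.array([w, x, y, z], dtype=float)
        n = np.linalg.norm(q)
        if n == 0.0 or not np.isfinite(n):
            raise ValueError("quaternion components must be finite and non-zero")
        self._q = q / n

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls) -> "Quaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, a) -> "Quaternion":
        a = np.asarray(a, dtype=float)
        return cls(a[0], a[1], a[2], a[3])

    @classmethod
    def from_axis_angle(cls, a: AxisAngle | None = None, *, axis=None,
                        angle_deg: float | None = None) -> "Quaternion":
        """Quaternion of a rotation by ``angle_deg`` about ``axis``.

        Accepts either an :class:`AxisAngle` or the pair ``axis, angle_deg``.
        """
        if a is not None:
            axis, angle_deg = a.axis, a.angle
        axis = np.asarray(axis, dtype=float)
        half = math.radians(angle_deg) / 2.0
        n = np.linalg.norm(axis)
        if n == 0.0:
            if abs(angle_deg) < 1e-12:
                return cls.identity()
            raise ValueError("axis must be non-zero for a non-zero angle")
        s = math.sin(half) / n
        return cls(math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s)

    @classmethod
    def from_rotation_vector(cls, rv_rad) -> "Quaternion":
        """Exponential map: rotation vector (radians) to quaternion."""
        rv = np.asarray(rv_rad, dtype=float)
        angle = np.linalg.norm(rv)
        if angle < 1e-300:
            return cls.identity()
        half = angle / 2.0
        s = math.sin(half) / angle
        return cls(math.cos(half), rv[0] * s, rv[1] * s, rv[2] * s)

    @classmethod
    def from_matrix(cls, m) -> "Quaternion":
        """Quaternion of a proper rotation matrix (Shepperd's method)."""
        m = np.asarray(m, dtype=float)
        tr = m[0, 0] + m[1, 1] + m[2, 2]
        if tr > 0:
            s = math.sqrt(tr + 1.0) * 2.0
            return cls(0.25 * s, (m[2, 1] - m[1, 2]) / s,
                       (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s)
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(m[i, i] - m[j, j] - m[k, k] + 1.0, 0.0)) * 2.0
        v = [0.0, 0.0, 0.0]
        v[i] = 0.25 * s
        v[j] = (m[j, i] + m[i, j]) / s
        v[k] = (m[k, i] + m[i, k]) / s
        return cls((m[k, j] - m[j, k]) / s, v[0], v[1], v[2])

    # -- accessors --------------------------------------------------------

    @property
    def w(self) -> float:
        return float(self._q[0])

    @property
    def x(self) -> float:
        return float(self._q[1])

    @property
    def y(self) -> float:
        return float(self._q[2])

    @property
    def z(self) -> float:
        return float(self._q[3])

    def as_array(self) -> np.ndarray:
        return self._q.copy()

    # -- algebra ----------------------------------------------------------

    def conjugate(self) -> "Quaternion":
        w, x, y, z = self._q
        return Quaternion(w, -x, -y, -z)

    inverse = conjugate  # unit quaternion

    def compose(self, other: "Quaternion") -> "Quaternion":
        """Hamilton product ``self * other``: apply ``other`` first, then
        ``self`` (both sensor-to-world maps)."""
        w1, x1, y1, z1 = self._q
        w2, x2, y2, z2 = other._q
        return Quaternion(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def __mul__(self, other: "Quaternion") -> "Quaternion":
        return self.compose(other)

    def rotate(self, v) -> np.ndarray:
        """Rotate a 3-vector from the local frame into the world frame."""
        v = np.asarray(v, dtype=float)
        w = self._q[0]
        u = self._q[1:]
        # v' = v + 2 w (u x v) + 2 u x (u x v)
        uv = np.cross(u, v)
        return v + 2.0 * (w * uv + np.cross(u, uv))

    def to_matrix(self) -> np.ndarray:
        w, x, y, z = self._q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def to_axis_angle(self) -> AxisAngle:
        """Axis-angle form with angle in [0, 180] degrees."""
        q = self._q if self._q[0] >= 0.0 else -self._q
        w = min(q[0], 1.0)
        angle = 2.0 * math.acos(w)
        s = math.sqrt(max(1.0 - w * w, 0.0))
        if s < 1e-12:
            return AxisAngle(np.array([1.0, 0.0, 0.0]), math.degrees(angle))
        return AxisAngle(q[1:] / s, math.degrees(angle))

    def to_rotation_vector(self) -> np.ndarray:
        """Logarithm map: rotation vector in radians, magnitude in [0, pi]."""
        aa = self.to_axis_angle()
        return aa.axis * math.radians(aa.angle)

    # -- comparison -------------------------------------------------------

    def angle_to(self, other: "Quaternion") -> float:
        """Magnitude in degrees of the relative rotation to ``other``."""
        rel = self.conjugate() * other
        w = abs(rel._q[0])
        s = float(np.linalg.norm(rel._q[1:]))
        # atan2 keeps full precision for small angles where acos would not
        return math.degrees(2.0 * math.atan2(s, w))

    def approx_equal(self, other: "Quaternion", tol_deg: float = 1e-6) -> bool:
        return self.angle_to(other) <= tol_deg

    def __repr__(self) -> str:
        w, x, y, z = self._q
        return f"Quaternion(w={w:+.6f}, x={x:+.6f}, y={y:+.6f}, z={z:+.6f})"


def heading_angle(q: Quaternion, forward=FORWARD) -> float:
    """Heading of an orientation, degrees in (-180, 180].

    The local ``forward`` axis is rotated into the world frame and projected
    onto the horizontal (x-z) plane; the heading is the angle of that
    projection from world ``+x``, positive about ``+y`` by the right-hand
    rule.  Raises :class:`DegenerateHeadingError` when the rotated forward
    axis is vertical (projection shorter than 1e-6).
    """
    f = q.rotate(forward)
    horiz = math.hypot(f[0], f[2])
    if horiz < _HEADING_EPS:
        raise DegenerateHeadingError(
            "forward axis is vertical; heading is undefined")
    # Positive rotation about +y carries +x toward -z.
    return math.degrees(math.atan2(-f[2], f[0]))


def rotate_heading(q: Quaternion, delta_deg: float) -> Quaternion:
    """Add ``delta_deg`` to the heading of ``q``.

    Pre-multiplies by a rotation about world ``+y``, which shifts heading
    while preserving the inclination of the orientation's vertical axis.
    """
    return Quaternion.from_axis_angle(axis=UP, angle_deg=delta_deg) * q
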