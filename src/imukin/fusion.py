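"""Gyroscope bias calibration and Mahony-filter orientation estimation.

The attitude of each sensor is tracked by a passive complementary (Mahony)
filter: the gyroscope is integrated for high-frequency accuracy while the
accelerometer, used purely as a gravity reference, corrects the low-frequency
tilt drift through a proportional-integral feedback term.  No magnetometer is
used, so the heading (rotation about the world vertical) is never corrected:
whatever heading the filter starts with persists, and is aligned across
sensors later by the calibration stage.

Gains default to a proportional gain of 1 and an integral gain of 0.3, which
bring the orientation estimate to steady state within about 3 s of a standing
start.  Gyroscope bias is estimated separately, by averaging a 10 s
stationary recording, and subtracted before the filter's own correction
terms; the bias store can be persisted and recalled across sessions (see
:mod:`imukin.io_formats`).

Internally angular rates are radians/s; the deg/s convention of
:class:`~imukin.imu_sim.ImuStream` is converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imu_sim import ImuStream
from .rotations import UP, Quaternion

__all__ = [
    "FusionSettings",
    "FilterState",
    "GyroBias",
    "estimate_gyro_bias",
    "mahony_step",
    "mahony_run",
    "static_orientation",
]

_G = 9.81


@dataclass(frozen=True)
class FusionSettings:
    """Mahony filter gains and accelerometer trust window.

    ``accel_gate`` is the (lo, hi) band, as multiples of g, outside which an
    accelerometer sample is considered dominated by linear acceleration and
    contributes no tilt correction.  ``integral_limit`` clamps the norm of
    the integral term (deg/s): the term models slow residual gyro bias,
    which after the 10 s bias calibration is far below 1 deg/s, and the
    clamp is the standard anti-windup safeguard that keeps a large initial
    orientation error from charging the integrator and delaying settling.
    """

    kp: float = 1.0
    ki: float = 0.3
    accel_gate: tuple[float, float] = (0.5, 1.5)
    integral_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("gains must be >= 0")
        if self.integral_limit <= 0:
            raise ValueError("integral_limit must be > 0")


@dataclass
class FilterState:
    """Current sensor-to-world estimate and PI integral accumulator."""

    q: Quaternion
    integral_error: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass(frozen=True)
class GyroBias:
    """Constant gyroscope offset for one sensor, deg/s per axis."""

    bias: np.ndarray
    computed_at: float = 0.0

    def __post_init__(self) -> None:
        b = np.asarray(self.bias, dtype=float)
        if not np.isfinite(b).all():
            raise ValueError("bias must be finite")
        object.__setattr__(self, "bias", b)

    @classmethod
    def zero(cls) -> "GyroBias":
        return cls(np.zeros(3))


def estimate_gyro_bias(stream: ImuStream, duration: float = 10.0) -> GyroBias:
    """Per-axis mean of the gyroscope over the first ``duration`` seconds.

    The stream must be stationary (caller-asserted) and at least ``duration``
    long.  Averaging 10 s of stationary data estimates the constant offset to
    well under the sensor's noise floor.
    """
    if stream.duration + 1e-9 < duration:
        raise ValueError(
            f"stream covers {stream.duration:.2f} s < required {duration:.2f} s")
    m = stream.t <= stream.t[0] + duration + 1e-9
    return GyroBias(bias=stream.gyro[m].mean(axis=0),
                    computed_at=float(stream.t[0]))


def mahony_step(state: FilterState, accel: np.ndarray, gyro_dps: np.ndarray,
                dt: float, settings: FusionSettings,
                bias: GyroBias) -> FilterState:
    """Advance the filter by one sample.

    The innovation is ``e = a_hat x v_hat`` where ``a_hat`` is the normalized
    accelerometer reading and ``v_hat`` the gravity-reaction direction the
    current estimate predicts in the sensor frame; ``e`` feeds proportional
    and integral corrections added to the bias-compensated gyro rate, which
    is then integrated by the quaternion exponential and renormalized.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    a = np.asarray(accel, dtype=float)
    norm = float(np.linalg.norm(a))
    lo, hi = settings.accel_gate
    integral = state.integral_error
    if lo * _G <= norm <= hi * _G:
        a_hat = a / norm
        # direction the accelerometer should read (opposite gravity), in the
        # sensor frame predicted by the current estimate
        v_hat = state.q.conjugate().rotate(UP)
        e = np.cross(a_hat, v_hat)
        integral = integral + settings.ki * e * dt
        lim = math.radians(settings.integral_limit)
        norm_i = float(np.linalg.norm(integral))
        if norm_i > lim:
            integral = integral * (lim / norm_i)
    else:
        e = np.zeros(3)
    omega = np.radians(np.asarray(gyro_dps, dtype=float) - bias.bias)
    omega_corr = omega + settings.kp * e + integral
    q = state.q * Quaternion.from_rotation_vector(omega_corr * dt)
    return FilterState(q=q, integral_error=integral)


def trapezoid_rates(gyro: np.ndarray) -> np.ndarray:
    """Average consecutive gyro samples for run-level integration.

    Integrating sample ``i`` over the interval ending at ``t_i`` with the
    instantaneous rate is only first-order accurate; using the mean of
    samples ``i-1`` and ``i`` (trapezoid rule) removes most of the
    truncation error at low sampling rates without changing the per-step
    filter contract.
    """
    g = np.asarray(gyro, dtype=float)
    if len(g) < 2:
        return g.copy()
    out = g.copy()
    out[1:] = 0.5 * (g[:-1] + g[1:])
    return out


def mahony_run(stream: ImuStream, settings: FusionSettings, bias: GyroBias,
               q0: Quaternion) -> list[Quaternion]:
    """Fold :func:`mahony_step` over a stream starting from ``q0``.

    Returns one orientation per sample; the first entry is ``q0`` updated by
    the first sample over one sampling interval.  Gyro rates are trapezoid-
    averaged across consecutive samples (see :func:`trapezoid_rates`).
    """
    dt = 1.0 / stream.rate
    state = FilterState(q=q0)
    out: list[Quaternion] = []
    for a, g in zip(stream.accel, trapezoid_rates(stream.gyro)):
        state = mahony_step(state, a, g, dt, settings, bias)
        out.append(state.q)
    return out


def static_orientation(stream: ImuStream, settings: FusionSettings,
                       bias: GyroBias, min_duration: float = 3.0) -> Quaternion:
    """Orientation of a stationary sensor from standing data.

    Runs the filter from the identity over the stream and returns the final
    estimate.  Only the inclination is meaningful: with no magnetometer the
    heading component is arbitrary and is fixed later by heading alignment.
    """
    if stream.duration + 1e-9 < min_duration:
        raise ValueError(
            f"static stream covers {stream.duration:.2f} s; "
            f"need at least {min_duration:.2f} s")
    return mahony_run(stream, settings, bias, Quaternion.identity())[-1]
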