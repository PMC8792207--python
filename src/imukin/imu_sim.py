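"""Synthetic IMU data generation from analytic joint trajectories.

Given a skeleton model and a joint-angle trajectory, this module produces the
accelerometer and gyroscope streams a body-worn IMU on each segment would
record, so the full fusion + calibration + inverse-kinematics chain can be
exercised and evaluated without hardware.

Measurement model
-----------------
With ``q(t)`` the sensor-to-world orientation of a sensor (segment
orientation composed with its fixed mounting rotation):

* gyroscope: the sensor-frame angular velocity, obtained from
  central-differenced quaternions (``omega = 2 vec(q* . dq/dt)`` evaluated via
  the relative-rotation logarithm over two sampling intervals), plus a
  constant per-sensor bias and white noise;
* accelerometer: the specific force ``q(t)^T (a_lin - g)`` in the sensor
  frame with the linear acceleration ``a_lin`` taken as zero -- the skeleton
  has no translational coordinates and the fusion stage treats the
  accelerometer purely as a gravity reference.  A stationary, level sensor
  therefore reads +9.81 m/s^2 along its up axis.

Noise defaults are the per-axis standard deviations measured from a
stationary sensor of the class this package targets: accelerometer
(0.0155, 0.0244, 0.254) m/s^2 and gyroscope (0.0742, 0.0583, 0.0369) deg/s.
All randomness flows from the :class:`NoiseModel` seed; per-sensor
sub-streams are spawned deterministically so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .rotations import GRAVITY, Quaternion
from .skeleton import Pose, SkeletonModel, clamp_to_limits, forward_kinematics

__all__ = [
    "ACCEL_NOISE_STD",
    "GYRO_NOISE_STD",
    "NoiseModel",
    "ImuStream",
    "Trajectory",
    "static_trajectory",
    "gait_trajectory",
    "synthesize",
    "trajectory_record",
]

#: Default accelerometer white-noise standard deviation per axis, m/s^2.
ACCEL_NOISE_STD = np.array([0.0155, 0.0244, 0.254])
#: Default gyroscope white-noise standard deviation per axis, deg/s.
GYRO_NOISE_STD = np.array([0.0742, 0.0583, 0.0369])


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor-noise description.

    ``gyro_bias`` maps sensor ids to a constant per-axis bias in deg/s;
    sensors not listed get zero bias.  ``seed`` drives all noise draws.
    """

    accel_std: np.ndarray = field(default_factory=lambda: ACCEL_NOISE_STD.copy())
    gyro_std: np.ndarray = field(default_factory=lambda: GYRO_NOISE_STD.copy())
    gyro_bias: Mapping[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.accel_std, dtype=float)
        g = np.asarray(self.gyro_std, dtype=float)
        if (a < 0).any() or (g < 0).any():
            raise ValueError("noise standard deviations must be >= 0")
        object.__setattr__(self, "accel_std", a)
        object.__setattr__(self, "gyro_std", g)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(accel_std=np.zeros(3), gyro_std=np.zeros(3))


@dataclass(frozen=True)
class ImuStream:
    """Uniformly sampled accelerometer/gyroscope stream for one sensor.

    ``accel`` is specific force in m/s^2, ``gyro`` angular velocity in deg/s,
    both in the sensor frame, shape (n, 3).
    """

    sensor_id: str
    rate: float
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if (dt <= 0).any():
                raise ValueError("timestamps must be strictly increasing")
            if np.abs(dt - 1.0 / self.rate).max() > 0.01 / self.rate:
                raise ValueError("timestamps must be uniform at the stated rate")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "accel", np.asarray(self.accel, dtype=float))
        object.__setattr__(self, "gyro", np.asarray(self.gyro, dtype=float))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def slice_time(self, t_lo: float, t_hi: float) -> "ImuStream":
        m = (self.t >= t_lo) & (self.t <= t_hi)
        return ImuStream(self.sensor_id, self.rate, self.t[m],
                         self.accel[m], self.gyro[m])


@dataclass(frozen=True)
class Trajectory:
    """Per-coordinate joint-angle functions of time, in degrees."""

    funcs: Mapping[str, Callable[[np.ndarray], np.ndarray]]
    duration: float
    tag: str = ""

    def pose_at(self, model: SkeletonModel, t: float) -> Pose:
        coords = {name: float(f(np.asarray(t))) for name, f in self.funcs.items()}
        return clamp_to_limits(model, model.pose_from_dict(coords))

    def sample(self, model: SkeletonModel, times: np.ndarray) -> np.ndarray:
        """(frames x model coordinates) matrix of clamped angles in degrees."""
        names = model.coordinate_names
        out = np.zeros((len(times), len(names)))
        for name, f in self.funcs.items():
            if name not in names:
                raise KeyError(f"trajectory coordinate {name!r} not in model")
            out[:, names.index(name)] = f(times)
        from .skeleton import clamp_matrix
        return clamp_matrix(model, names, out)


def static_trajectory(duration: float,
                      pose: Mapping[str, float] | None = None,
                      tag: str = "static") -> Trajectory:
    """Constant-pose trajectory (neutral standing by default)."""
    pose = dict(pose or {})
    funcs = {name: (lambda t, v=val: np.full_like(np.asarray(t, dtype=float), v))
             for name, val in pose.items()}
    return Trajectory(funcs=funcs, duration=duration, tag=tag)


# Default phase lags (fraction of a cycle) giving a gait-like coordination:
# the knee peak trails the hip peak by a quarter cycle and the ankle is in
# anti-phase with the hip; left-side coordinates are shifted half a cycle.
_PHASE_BY_KIND = {"hip": 0.0, "knee": -0.25, "ankle": -0.5}


def _phase_for(coordinate: str) -> float:
    lag = 0.0
    for kind, p in _PHASE_BY_KIND.items():
        if coordinate.startswith(kind):
            lag = p
            break
    if coordinate.endswith("_l"):
        lag += 0.5
    return lag


def gait_trajectory(period: float, amplitudes: Mapping[str, float],
                    duration: float,
                    means: Mapping[str, float] | None = None,
                    ramp: float = 2.0) -> Trajectory:
    """Sinusoidal gait-like trajectory starting from quiet standing.

    Each coordinate follows ``r(t) (mean + A sin(2 pi (t/period + phase)))``
    with phases chosen so the knee peaks a quarter cycle after the hip and
    the two legs alternate.  ``r(t)`` is a smoothstep ramp from 0 to 1 over
    the first ``ramp`` seconds, emulating a subject who stands in the
    calibration pose and then starts walking; set ``ramp=0`` for an
    immediately periodic signal.  Deterministic: identical arguments give
    identical samples.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    means = dict(means or {})
    funcs = {}
    for name, amp in amplitudes.items():
        phase = _phase_for(name)
        mean = means.get(name, 0.0)

        def f(t, A=amp, ph=phase, mu=mean):
            t = np.asarray(t, dtype=float)
            if ramp > 0:
                u = np.clip(t / ramp, 0.0, 1.0)
                r = u * u * (3.0 - 2.0 * u)
            else:
                r = 1.0
            return r * (mu + A * np.sin(2.0 * math.pi * (t / period + ph)))

        funcs[name] = f
    return Trajectory(funcs=funcs, duration=duration, tag="gait")


def _sensor_quaternions(model: SkeletonModel, traj: Trajectory,
                        times: np.ndarray,
                        segments: Iterable[str]) -> dict[str, list[Quaternion]]:
    angles = traj.sample(model, times)
    names = model.coordinate_names
    out: dict[str, list[Quaternion]] = {s: [] for s in segments}
    for row in angles:
        fk = forward_kinematics(model, Pose(names, row))
        for s in out:
            out[s].append(fk[s] * model.mounting[s])
    return out


def synthesize(model: SkeletonModel, traj: Trajectory, rate: float,
               noise: NoiseModel,
               segments: Iterable[str] | None = None) -> dict[str, ImuStream]:
    """Simulate one IMU stream per tracked segment.

    Angular velocity is derived from central-differenced sensor quaternions
    (one-sided at the endpoints), which is accurate to well under the noise
    floor at the default 100 Hz; the specific force is the rotated gravity
    reaction (no linear acceleration, see module docstring).
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    segments = tuple(segments) if segments is not None else model.segments
    for s in segments:
        if s not in model.segments:
            raise KeyError(f"unknown segment {s!r}")
    n = int(round(traj.duration * rate)) + 1
    times = np.arange(n) / rate
    quats = _sensor_quaternions(model, traj, times, segments)
    minus_g = -GRAVITY
    root = np.random.SeedSequence(noise.seed)
    children = root.spawn(len(segments))
    streams: dict[str, ImuStream] = {}
    for seg, seq in zip(segments, children):
        qs = quats[seg]
        rng = np.random.default_rng(seq)
        accel = np.empty((n, 3))
        gyro = np.empty((n, 3))
        for i, q in enumerate(qs):
            accel[i] = q.conjugate().rotate(minus_g)
            lo, hi = max(i - 1, 0), min(i + 1, n - 1)
            rel = qs[lo].conjugate() * qs[hi]
            omega = rel.to_rotation_vector() * (rate / (hi - lo))
            gyro[i] = np.degrees(omega)
        bias = np.asarray(noise.gyro_bias.get(seg, np.zeros(3)), dtype=float)
        accel += rng.normal(0.0, 1.0, size=(n, 3)) * noise.accel_std
        gyro += bias + rng.normal(0.0, 1.0, size=(n, 3)) * noise.gyro_std
        streams[seg] = ImuStream(seg, rate, times, accel, gyro)
    return streams


def trajectory_record(model: SkeletonModel, traj: Trajectory, rate: float):
    """Ground-truth coordinates of a trajectory as a MotionRecord."""
    from .ik import MotionRecord
    n = int(round(traj.duration * rate)) + 1
    times = np.arange(n) / rate
    data = traj.sample(model, times)
    return MotionRecord(time=times, data=data,
                        names=model.coordinate_names, rate=rate)
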