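"""Streaming orchestration: sensor fusion stage feeding an IK stage.

The on-body architecture has two logical stages: stage 1 consumes every IMU
sample and keeps one Mahony filter per sensor up to date; stage 2 fires at a
configured computation rate, reads the most recent orientation of every
sensor, and solves one inverse-kinematics frame.  The stages are coupled by a
*latest-value exchange*: writing never blocks, reading always returns the
newest frame, intermediate frames may be skipped but are never reordered.

At desk scale the contract is executed single-threaded on a simulated clock:
samples are consumed in timestamp order and the IK stage fires whenever its
next scheduled time has been reached.  When the IK rate equals the stream
rate, every sample is solved exactly once and the result is bit-identical to
the offline mode, which runs fusion and then IK over every recorded sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibrationState
from .fusion import FilterState, FusionSettings, mahony_step, trapezoid_rates
from .ik import IKSettings, MotionRecord, solve_sequence
from .imu_sim import ImuStream
from .rotations import Quaternion
from .skeleton import ROOT_SEGMENT, SkeletonModel

__all__ = [
    "PipelineConfig",
    "LatestValueExchange",
    "run_online",
    "run_offline",
]


class LatestValueExchange:
    """Non-blocking single-slot handoff between the two stages.

    ``put`` overwrites the slot (never blocks); ``get`` returns the newest
    value.  Timestamps must be non-decreasing, so a newer frame is never
    followed by an older one.
    """

    def __init__(self) -> None:
        self._t = -np.inf
        self._value = None

    def put(self, t: float, value) -> None:
        if t < self._t:
            raise ValueError("latest-value exchange received an older frame")
        self._t = t
        self._value = value

    def get(self):
        return self._t, self._value


@dataclass(frozen=True)
class PipelineConfig:
    """Which segments to track and how fast to compute kinematics."""

    model: SkeletonModel
    segments: tuple[str, ...]
    ik_rate: float = 30.0
    mode: str = "online"
    seed: int = 0
    fusion: FusionSettings = field(default_factory=FusionSettings)
    ik: IKSettings = field(default_factory=IKSettings)

    def __post_init__(self) -> None:
        if self.ik_rate <= 0:
            raise ValueError("computation rate must be > 0")
        unknown = [s for s in self.segments if s not in self.model.segments]
        if unknown:
            raise ValueError(f"segments not in model: {unknown}")
        if ROOT_SEGMENT not in self.segments:
            raise ValueError("pelvis (base segment) must be tracked")
        if self.mode not in ("online", "offline"):
            raise ValueError("mode must be 'online' or 'offline'")


def _check_calibrated(calibration: CalibrationState | None,
                      segments) -> None:
    if calibration is None:
        raise RuntimeError("no calibration available; run pose calibration first")
    missing = [s for s in segments if s not in calibration.sensors]
    if missing:
        raise RuntimeError(f"calibration missing sensor(s) {missing}")


def run_online(config: PipelineConfig, streams: Mapping[str, ImuStream],
               calibration: CalibrationState) -> MotionRecord:
    """Two-stage streaming run on a simulated clock.

    Stage 1 updates one filter per sensor for every sample in timestamp
    order; stage 2 fires at ``config.ik_rate`` starting from the first common
    timestamp, snapshotting the latest orientations through the exchange.
    The record's timestamps are the stage-2 fire times.
    """
    _check_calibrated(calibration, config.segments)
    segs = config.segments
    states = {s: FilterState(q=calibration.sensors[s].initial_orientation)
              for s in segs}
    exchanges = {s: LatestValueExchange() for s in segs}
    cursors = {s: 0 for s in segs}
    rates = {s: trapezoid_rates(streams[s].gyro) for s in segs}
    t0 = max(float(streams[s].t[0]) for s in segs)
    t_end = min(float(streams[s].t[-1]) for s in segs)
    dt_ik = 1.0 / config.ik_rate
    frames: list[tuple[float, dict[str, Quaternion]]] = []
    eps = 1e-9
    k = 0
    while True:
        fire = t0 + k * dt_ik
        if fire > t_end + eps:
            break
        for s in segs:
            st = streams[s]
            i = cursors[s]
            dt = 1.0 / st.rate
            while i < len(st) and st.t[i] <= fire + eps:
                states[s] = mahony_step(states[s], st.accel[i], rates[s][i],
                                        dt, config.fusion,
                                        calibration.sensors[s].bias)
                exchanges[s].put(float(st.t[i]), states[s].q)
                i += 1
            cursors[s] = i
        snapshot = {}
        ready = True
        for s in segs:
            _, q = exchanges[s].get()
            if q is None:
                ready = False
                break
            snapshot[s] = q
        if ready:
            frames.append((fire, snapshot))
        k += 1
    if not frames:
        return MotionRecord(time=np.zeros(0),
                            data=np.zeros((0, len(config.model.coordinate_names))),
                            names=config.model.coordinate_names,
                            rate=config.ik_rate)
    return solve_sequence(config.model, frames, calibration, config.ik,
                          rate=config.ik_rate)


def run_offline(config: PipelineConfig, streams: Mapping[str, ImuStream],
                calibration: CalibrationState) -> MotionRecord:
    """Batch run: fusion then IK over every recorded sample.

    All streams must share the same timestamps (one sample set per frame).
    """
    _check_calibrated(calibration, config.segments)
    segs = config.segments
    ref = streams[segs[0]]
    for s in segs[1:]:
        if len(streams[s]) != len(ref) or (
                len(ref) and np.abs(streams[s].t - ref.t).max() > 1e-9):
            raise ValueError("offline mode requires a common time base")
    if len(ref) == 0:
        return MotionRecord(time=np.zeros(0),
                            data=np.zeros((0, len(config.model.coordinate_names))),
                            names=config.model.coordinate_names,
                            rate=ref.rate or config.ik_rate)
    orientations = {}
    for s in segs:
        st = streams[s]
        state = FilterState(q=calibration.sensors[s].initial_orientation)
        dt = 1.0 / st.rate
        series = []
        for a, g in zip(st.accel, trapezoid_rates(st.gyro)):
            state = mahony_step(state, a, g, dt, config.fusion,
                                calibration.sensors[s].bias)
            series.append(state.q)
        orientations[s] = series
    frames = [(float(ref.t[i]), {s: orientations[s][i] for s in segs})
              for i in range(len(ref))]
    return solve_sequence(config.model, frames, calibration, config.ik,
                          rate=ref.rate)
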